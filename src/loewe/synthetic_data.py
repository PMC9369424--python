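"""Synthetic per-animal behavioral datasets for end-to-end testing.

No raw data from the neuropathic-pain study are deposited, so this module
generates per-animal records with the statistical structure the analysis
assumes: a chronic-constriction-injury (CCI) cohort with n = 6 animals per
treatment group, von Frey paw-withdrawal thresholds bounded by the 0.2 and
6.84 g filaments, acetone response counts over 2 min, rotarod latencies
capped at 300 s, bar latencies capped at 120 s, intrathecal doses spanning
1-178 nmol, and a 1:1 fixed-ratio combination ray.

Each animal receives a pre-CCI baseline, an allodynic post-CCI pre-drug
baseline (lower threshold, more acetone responses), and a latent drug
effect drawn from Hill-curve ground truth (single drugs) or from the
dose-equivalence additive surface (combination ray, optionally potency-
shifted to embed true synergy).  Gaussian noise is applied on the %MPE
scale and back-transformed through the inverse normalizations to raw
assay units, clipped to assay bounds; counts are rounded.  Side-effect
assays (rotarod, bar, open field) carry zero latent drug effect by
default, with an optional hook.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .additive_model import AdditiveSurface, CombinationDesign, additive_effect
from .dose_response import HillParams, hill_effect
from .normalization import (
    Assay,
    BAR_CUTOFF_S,
    PWT_CUTOFF_G,
    ROTAROD_CUTOFF_S,
    invert_mpe_bar,
    invert_mpe_reduction,
    invert_mpe_threshold,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate",
           "vehicle_stability_check", "DEFAULT_TRUTH"]

PWT_FLOOR_G = 0.2  # weakest von Frey filament

#: ground-truth Hill parameters per assay: (drug_a (CBD-like, lower max),
#: drug_b (THC-like, higher max)); side-effect assays have no dose effect
DEFAULT_TRUTH: dict[str, tuple[HillParams, HillParams]] = {
    "mechanical_pwt": (
        HillParams(emax=79.0, ed50=20.0, hill=1.5, label="CBD/mechanical_pwt"),
        HillParams(emax=85.0, ed50=14.0, hill=2.6, label="THC/mechanical_pwt"),
    ),
    "acetone": (
        HillParams(emax=27.0, ed50=11.0, hill=2.2, label="CBD/acetone"),
        HillParams(emax=52.0, ed50=21.0, hill=1.7, label="THC/acetone"),
    ),
}

#: (pre-CCI mean, pre-CCI sd, post-CCI mean, post-CCI sd) in raw assay units
DEFAULT_BASELINES: dict[str, tuple[float, float, float, float]] = {
    "mechanical_pwt": (3.5, 0.5, 0.6, 0.15),
    "acetone": (0.5, 0.5, 6.0, 1.0),
    "rotarod": (280.0, 15.0, 270.0, 15.0),
    "bar": (5.0, 2.0, 5.0, 2.0),
    "open_field": (60.0, 10.0, 55.0, 10.0),
}

_ASSAY_BOUND = {
    "mechanical_pwt": PWT_CUTOFF_G,
    "rotarod": ROTAROD_CUTOFF_S,
    "bar": BAR_CUTOFF_S,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and ground-truth settings for the generator.

    ``interaction_shift`` multiplies the dose axis of the combination
    ray's latent curve: 1.0 embeds exact additivity, values below 1 make
    the combination proportionally more potent than additive (true
    synergy), values above 1 embed antagonism.  ``noise_sd`` is the
    residual SD on the %MPE scale.  ``vehicle_shift`` adds a constant
    latent %MPE to the vehicle group (0 = the stability contract).
    """

    seed: int = 0
    n_per_group: int = 6
    doses: tuple[float, ...] = (1.0, 3.2, 10.0, 32.0, 100.0, 178.0)
    combination_doses: tuple[float, ...] = (1.5, 4.8, 15.3, 48.6, 153.0)
    assays: tuple[str, ...] = ("mechanical_pwt", "acetone")
    truth: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    interaction_shift: float = 1.0
    noise_sd: float = 10.0
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    design: CombinationDesign = CombinationDesign()
    timepoints_h: tuple[float, ...] = (1.0, 2.0)
    include_vehicle: bool = True
    vehicle_shift: float = 0.0
    acetone_poisson: bool = False
    side_effect_hook: dict = field(default_factory=dict)  # assay -> HillParams

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        if any(d <= 0 for d in self.doses + self.combination_doses):
            raise ValueError("doses must be positive")
        if self.interaction_shift <= 0:
            raise ValueError("interaction_shift must be positive")
        for assay in self.assays:
            Assay(assay)
            mu_pre, _, mu_post, _ = self.baselines[assay]
            bound = _ASSAY_BOUND.get(assay)
            if mu_pre < 0 or mu_post < 0 or (
                bound is not None and (mu_pre > bound or mu_post > bound)
            ):
                raise ValueError(f"baseline means out of range for {assay}")


@dataclass
class SyntheticDataset:
    """Generated records plus the ground truth that produced them.

    ``records`` uses the per-animal CSV dialect (animal_id, group,
    drug_a_dose_nmol, drug_b_dose_nmol, assay, timepoint_h, pre_drug,
    post_drug); ``pre_cci`` holds the pre-surgery baselines; ``latent``
    the noise-free %MPE effect per group and assay.
    """

    records: pd.DataFrame
    config: GeneratorConfig
    pre_cci: pd.DataFrame
    latent: pd.DataFrame

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _truth_surface(cfg: GeneratorConfig, assay: str) -> AdditiveSurface:
    a, b = cfg.truth[assay]
    return AdditiveSurface(params_a=a, params_b=b, design=cfg.design)


def _latent_mpe(cfg: GeneratorConfig, assay: str, dose_a: float,
                dose_b: float) -> float:
    """Noise-free %MPE for a treatment in one assay."""
    if assay in cfg.side_effect_hook:
        return float(hill_effect(cfg.side_effect_hook[assay], dose_a + dose_b))
    if assay not in cfg.truth:
        return 0.0  # side-effect assay: no dose dependence
    truth_a, truth_b = cfg.truth[assay]
    if dose_a > 0 and dose_b > 0:
        s = cfg.interaction_shift
        return additive_effect(_truth_surface(cfg, assay), dose_a / s, dose_b / s)
    if dose_a > 0:
        return float(hill_effect(truth_a, dose_a))
    if dose_b > 0:
        return float(hill_effect(truth_b, dose_b))
    return cfg.vehicle_shift


def _back_transform(assay: str, pre: float, mpe: float,
                    rng: np.random.Generator, poisson: bool) -> float:
    """Raw post-drug value realizing a %MPE score, clipped to assay bounds."""
    if assay == "mechanical_pwt":
        return float(np.clip(invert_mpe_threshold(pre, mpe), PWT_FLOOR_G,
                             PWT_CUTOFF_G))
    if assay == "acetone":
        mean = max(invert_mpe_reduction(pre, mpe), 0.0)
        return float(rng.poisson(mean)) if poisson else float(round(mean))
    if assay == "rotarod":
        return float(np.clip(invert_mpe_reduction(pre, mpe), 0.0,
                             ROTAROD_CUTOFF_S))
    if assay == "bar":
        return float(np.clip(invert_mpe_bar(pre, mpe), 0.0, BAR_CUTOFF_S))
    raise ValueError(f"no back-transform for assay {assay!r}")


def _draw_pre(assay: str, mu: float, sd: float, rng: np.random.Generator) -> float:
    bound = _ASSAY_BOUND.get(assay, np.inf)
    val = float(np.clip(rng.normal(mu, sd), 0.0, bound))
    if assay == "mechanical_pwt":
        val = max(val, PWT_FLOOR_G)
    if assay in ("acetone", "open_field"):
        val = max(round(val), 1.0 if assay == "acetone" else 0.0)
    return val


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full per-animal dataset from the ground-truth config."""
    rng = np.random.default_rng(config.seed)
    fa, fb = config.design.frac_a, config.design.frac_b

    groups: list[tuple[str, float, float]] = []
    if config.include_vehicle:
        groups.append(("vehicle", 0.0, 0.0))
    for d in config.doses:
        groups.append((f"A_{d:g}", d, 0.0))
    for d in config.doses:
        groups.append((f"B_{d:g}", 0.0, d))
    for d in config.combination_doses:
        groups.append((f"AB_{d:g}", fa * d, fb * d))

    rows, pre_rows, latent_rows = [], [], []
    animal_no = 0
    for group, dose_a, dose_b in groups:
        for _ in range(config.n_per_group):
            animal_no += 1
            aid = f"m{animal_no:03d}"
            for assay in config.assays:
                mu0, sd0, mu1, sd1 = config.baselines[assay]
                pre_surgery = _draw_pre(assay, mu0, sd0, rng)
                pre_drug = _draw_pre(assay, mu1, sd1, rng)
                pre_rows.append(
                    {"animal_id": aid, "assay": assay, "pre_cci": pre_surgery}
                )
                latent = _latent_mpe(config, assay, dose_a, dose_b)
                for tp in config.timepoints_h:
                    if assay == "open_field":
                        post = max(round(pre_drug + rng.normal(0.0, sd1)), 0.0)
                    else:
                        mpe = latent + rng.normal(0.0, config.noise_sd)
                        post = _back_transform(assay, pre_drug, mpe, rng,
                                               config.acetone_poisson)
                    rows.append({
                        "animal_id": aid,
                        "group": group,
                        "drug_a_dose_nmol": dose_a,
                        "drug_b_dose_nmol": dose_b,
                        "assay": assay,
                        "timepoint_h": tp,
                        "pre_drug": pre_drug,
                        "post_drug": post,
                    })
        for assay in config.assays:
            latent_rows.append({
                "group": group, "assay": assay,
                "dose_a": dose_a, "dose_b": dose_b,
                "latent_mpe": _latent_mpe(config, assay, dose_a, dose_b),
            })

    return SyntheticDataset(
        records=pd.DataFrame(rows),
        config=config,
        pre_cci=pd.DataFrame(pre_rows),
        latent=pd.DataFrame(latent_rows),
    )


def vehicle_stability_check(dataset: SyntheticDataset,
                            tol_multiple: float = 4.0) -> bool:
    """True when the vehicle group's mean %MPE is within noise of zero.

    The generator's contract is that vehicle injections have no latent
    effect (post-drug scores fluctuate around the pre-drug baseline).
    The check compares the vehicle mean %MPE against ``tol_multiple``
    standard errors of the configured noise (plus a small allowance for
    count rounding).
    """
    from .normalization import normalize_records

    veh = dataset.records[dataset.records["group"] == "vehicle"]
    if veh.empty:
        raise ValueError("dataset has no vehicle group")
    norm = normalize_records(veh)
    norm = norm.dropna(subset=["mpe"])
    n = len(norm)
    se = dataset.config.noise_sd / np.sqrt(max(n, 1))
    tol = tol_multiple * se + 1.0  # +1 %MPE for rounding/clipping slack
    return bool(abs(norm["mpe"].mean()) <= tol)
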