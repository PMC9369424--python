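"""End-to-end analysis pipeline: records -> fits -> surface -> synergy.

Stage functions operate on the per-animal records table and return plain
dicts/dataclasses so the CLI can serialize them; each stage is re-runnable
from intermediate files.  Drug roles on the additive surface are assigned
by maximal effect (larger E_max becomes drug B) and the assignment is
recorded in the output, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .additive_model import (
    AdditiveSurface,
    CombinationDesign,
    combination_report,
    make_surface,
    predicted_ed50,
)
from .dose_response import (
    DoseResponseDataset,
    HillParams,
    UnidentifiableFitError,
    fit_hill,
)
from .isoboles import DEFAULT_LEVELS, isobole_family, linear_isobole
from .normalization import normalize_records
from .synergy_test import ED50Estimate, compare_ed50s

log = logging.getLogger("loewe")

__all__ = ["RunConfig", "extract_dose_response", "run_single_drug",
           "run_combination"]


@dataclass
class RunConfig:
    """Settings for a pipeline run."""

    assays: tuple[str, ...] = ("mechanical_pwt", "acetone")
    design: CombinationDesign = field(default_factory=CombinationDesign)
    levels: tuple[float, ...] = DEFAULT_LEVELS
    alpha: float = 0.05
    dof_convention: str = "welch"
    label_a: str = "CBD"
    label_b: str = "THC"
    #: "emax": assign drug B (higher maximum) from the fitted maxima;
    #: "fixed": keep label_b as drug B regardless of sampling noise in the
    #: fitted maxima (the convention when the ordering is known a priori
    #: from the single-drug stage).
    role_assignment: str = "emax"


def extract_dose_response(
    norm: pd.DataFrame, assay: str, arm: str, label: str = ""
) -> DoseResponseDataset:
    """Pull one treatment arm's (dose, %MPE) observations.

    ``arm`` is ``"a"`` (drug A alone), ``"b"`` (drug B alone) or ``"ab"``
    (the fixed-ratio combination, dose = total).
    """
    df = norm[norm["assay"] == assay]
    da, db = df["drug_a_dose_nmol"].fillna(0), df["drug_b_dose_nmol"].fillna(0)
    if arm == "a":
        sel = (da > 0) & (db == 0)
        dose = da
    elif arm == "b":
        sel = (da == 0) & (db > 0)
        dose = db
    elif arm == "ab":
        sel = (da > 0) & (db > 0)
        dose = da + db
    else:
        raise ValueError(f"unknown arm {arm!r}")
    df = df[sel]
    if df.empty:
        raise ValueError(f"no records for arm {arm!r} in assay {assay!r}")
    return DoseResponseDataset(
        drug_label=label or arm,
        assay=assay,
        doses=dose[sel].to_numpy(),
        effects=df["mpe"].to_numpy(),
        animal_ids=df["animal_id"].tolist(),
    )


def _dose_dependence_p(data: DoseResponseDataset) -> float:
    """p-value of the slope of %MPE on log10(dose): a flatness screen."""
    res = _stats.linregress(np.log10(data.doses), data.effects)
    return float(res.pvalue)


def run_single_drug(records: pd.DataFrame, config: RunConfig) -> dict:
    """Normalize and fit each single-drug arm per assay.

    Arms with no detectable dose dependence (flat side-effect profiles)
    are skipped with a note rather than force-fit; other arms failing to
    fit are reported per-item and the run continues.
    """
    if records.empty:
        raise ValueError("empty records input")
    norm = normalize_records(records)
    out: dict = {"fits": {}, "notes": []}
    for assay in config.assays:
        for arm, label in (("a", config.label_a), ("b", config.label_b)):
            key = f"{label}/{assay}"
            try:
                data = extract_dose_response(norm, assay, arm, label)
            except ValueError as exc:
                out["notes"].append(f"{key}: {exc}")
                continue
            if _dose_dependence_p(data) >= 0.05:
                out["notes"].append(
                    f"{key}: no dose dependence detected; fit skipped"
                )
                continue
            try:
                fit = fit_hill(data)
            except (UnidentifiableFitError, ValueError) as exc:
                out["notes"].append(f"{key}: fit failed ({exc})")
                continue
            out["fits"][key] = fit
            log.info("fit %s: ED50=%.3g Emax=%.3g hill=%.3g",
                     key, fit.ed50, fit.emax, fit.hill)
    return out


def run_combination(
    records: pd.DataFrame,
    config: RunConfig,
    single_fits: dict[str, HillParams] | None = None,
) -> dict:
    """Predicted-additive surface, experimental combination fit, isoboles
    and the synergy test, per assay.

    Requires single-drug fits (computed here if not supplied) plus
    combination-ray records.  Output maps each assay to a bundle with the
    surface's role assignment, the ray report, the isobole family, the
    linear reference isobole and the ``SynergyReport``.
    """
    if single_fits is None:
        single_fits = run_single_drug(records, config)["fits"]
    norm = normalize_records(records)
    out: dict = {}
    for assay in config.assays:
        key_a, key_b = f"{config.label_a}/{assay}", f"{config.label_b}/{assay}"
        if key_a not in single_fits or key_b not in single_fits:
            out[assay] = {"error": f"missing single-drug fits for {assay}"}
            continue
        try:
            combo = extract_dose_response(
                norm, assay, "ab", f"{config.label_b}:{config.label_a}"
            )
        except ValueError:
            out[assay] = {
                "error": f"missing combination-ray records for {assay}: "
                "supply records with both doses positive"
            }
            continue
        if config.role_assignment == "fixed":
            surface = AdditiveSurface(
                params_a=single_fits[key_a], params_b=single_fits[key_b],
                design=config.design, check_roles=False,
            )
        elif config.role_assignment == "emax":
            surface = make_surface(single_fits[key_a], single_fits[key_b],
                                   design=config.design)
        else:
            raise ValueError(
                f"unknown role_assignment {config.role_assignment!r}"
            )
        role_b = (key_b if surface.params_b is single_fits[key_b] else key_a)
        log.info("%s: drug B (higher Emax) = %s", assay, role_b)
        exp_fit = fit_hill(combo)
        pred = predicted_ed50(surface)
        report = compare_ed50s(
            ED50Estimate(exp_fit.ed50, exp_fit.se_ed50, exp_fit.dof),
            ED50Estimate(
                pred.ed50, pred.se,
                surface.params_a.dof + surface.params_b.dof or 1,
            ),
            alpha=config.alpha,
            assay=assay,
            dof_convention=config.dof_convention,
        )
        levels = [lv for lv in config.levels if lv < surface.params_b.emax]
        out[assay] = {
            "surface": surface,
            "role_b": role_b,
            "experimental_fit": exp_fit,
            "predicted": pred,
            "report": combination_report(surface, assay, exp_fit),
            "synergy": report,
            "isoboles": isobole_family(surface, levels),
            "linear_isobole": linear_isobole(
                surface.params_a.ed50,
                surface.params_b.ed50,
                np.linspace(0.0, 1.25 * surface.params_a.ed50, 101),
            ),
        }
    return out
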