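"""Sigmoidal (Hill) dose-response fitting on the %MPE scale.

The model is the three-parameter Hill function with the lower asymptote
fixed at 0 %MPE,

    E(d) = Emax / (1 + 10^(p * (log10(ED50) - log10(d)))),

equivalently ``Emax * d^p / (ED50^p + d^p)``: maximal effect ``Emax``
(%MPE), half-maximally effective dose ``ED50`` (nmol) and Hill slope ``p``.
Fitting is nonlinear least squares on individual animals' %MPE values with
ED50 parameterized on the log10 scale internally for stability; estimates
and their covariance are reported on the linear scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "HillParams",
    "DoseResponseDataset",
    "UnidentifiableFitError",
    "hill_effect",
    "inverse_hill",
    "fit_hill",
]

# pharmacologically meaningful region for the optimizer
EMAX_BOUNDS = (1e-6, 120.0)
ED50_BOUNDS = (0.1, 1000.0)
HILL_BOUNDS = (0.1, 10.0)


class UnidentifiableFitError(RuntimeError):
    """The dose-response fit did not converge or is rank-deficient."""


@dataclass
class HillParams:
    """Fitted Hill parameters for one drug (or fixed-ratio ray) and assay.

    ``cov`` is the 3x3 covariance of ``(emax, ed50, hill)`` on the linear
    scale; ``dof`` the residual degrees of freedom of the fit.
    """

    emax: float
    ed50: float
    hill: float
    se_emax: float = 0.0
    se_ed50: float = 0.0
    se_hill: float = 0.0
    cov: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    n_animals: int = 0
    dof: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.emax > 0 and self.ed50 > 0 and self.hill > 0):
            raise ValueError("emax, ed50 and hill must all be positive")
        if self.cov is None:
            # diagonal covariance from the SEs (all that a summary table gives)
            self.cov = np.diag([self.se_emax**2, self.se_ed50**2, self.se_hill**2])
        else:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.shape != (3, 3):
                raise ValueError("cov must be 3x3")
            if not np.allclose(self.cov, self.cov.T, atol=1e-10):
                raise ValueError("cov must be symmetric")
            if np.linalg.eigvalsh(self.cov).min() < -1e-8:
                raise ValueError("cov must be positive semi-definite")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.emax, self.ed50, self.hill])

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "emax": self.emax,
            "ed50": self.ed50,
            "hill": self.hill,
            "se_emax": self.se_emax,
            "se_ed50": self.se_ed50,
            "se_hill": self.se_hill,
            "cov": np.asarray(self.cov).tolist(),
            "n_animals": self.n_animals,
            "dof": self.dof,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(
            emax=d["emax"], ed50=d["ed50"], hill=d["hill"],
            se_emax=d.get("se_emax", 0.0), se_ed50=d.get("se_ed50", 0.0),
            se_hill=d.get("se_hill", 0.0),
            cov=np.asarray(d["cov"]) if d.get("cov") is not None else None,
            n_animals=d.get("n_animals", 0), dof=d.get("dof", 0),
            label=d.get("label", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HillParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DoseResponseDataset:
    """Per-animal %MPE observations across doses for one drug and assay.

    ``doses`` and ``effects`` are parallel arrays (one entry per animal);
    ``animal_ids`` is optional bookkeeping.
    """

    drug_label: str
    assay: str
    doses: np.ndarray
    effects: np.ndarray
    animal_ids: list | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.doses.shape != self.effects.shape:
            raise ValueError("doses and effects must be parallel arrays")
        if np.any(self.doses <= 0):
            raise ValueError("dose-response doses must be positive")

    @property
    def n_distinct_doses(self) -> int:
        return np.unique(self.doses).size


def hill_effect(params: HillParams, dose) -> np.ndarray | float:
    """Evaluate the Hill curve at ``dose`` (nmol); 0 at dose 0 (the limit)."""
    dose = np.asarray(dose, dtype=float)
    scalar = dose.ndim == 0
    dose = np.atleast_1d(dose)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = np.zeros_like(dose)
    pos = dose > 0
    out[pos] = params.emax / (
        1.0 + 10.0 ** (params.hill * (np.log10(params.ed50) - np.log10(dose[pos])))
    )
    return float(out[0]) if scalar else out


def inverse_hill(params: HillParams, effect: float) -> float:
    """Unique dose at which the Hill curve attains ``effect`` (%MPE).

    Closed form: ``ED50 * (E / (Emax - E))^(1/p)``.

    Raises
    ------
    ValueError
        If ``effect`` is outside the open interval (0, emax): the level is
        unreachable (the curve saturates below it) or degenerate.
    """
    if not 0.0 < effect < params.emax:
        raise ValueError(
            f"effect level {effect} unreachable: must lie in (0, {params.emax})"
        )
    return params.ed50 * (effect / (params.emax - effect)) ** (1.0 / params.hill)


def _model(dose, emax, log10_ed50, hill):
    dose = np.asarray(dose, dtype=float)
    return emax / (1.0 + 10.0 ** (hill * (log10_ed50 - np.log10(dose))))


def fit_hill(
    data: DoseResponseDataset,
    init: HillParams | None = None,
) -> HillParams:
    """Least-squares Hill fit to a per-animal dose-response dataset.

    Initialization (overridable through ``init``): ``emax`` at the maximum
    observed effect, ``ed50`` at the dose whose mean effect is nearest to
    half of it, ``hill = 1``.  The ED50 is optimized on the log10 scale;
    the reported covariance is transformed back to the linear scale with
    the Jacobian ``d(ed50)/d(log10 ed50) = ln(10) * ed50``.

    Raises
    ------
    UnidentifiableFitError
        On non-convergence, a rank-deficient Jacobian (e.g. flat data) or
        a fit pinned to the parameter bounds.
    """
    if data.n_distinct_doses < 4:
        raise ValueError(
            f"need >=4 distinct doses for a 3-parameter fit, got "
            f"{data.n_distinct_doses}"
        )
    doses, effects = data.doses, data.effects
    if init is not None:
        p0 = [init.emax, np.log10(init.ed50), init.hill]
    else:
        emax0 = float(np.max(effects))
        if emax0 <= 0:
            raise UnidentifiableFitError(
                f"no positive effect observed for {data.drug_label}/{data.assay}: "
                "dose-response unidentifiable"
            )
        # dose whose group-mean effect is nearest emax0/2
        uniq = np.unique(doses)
        means = np.array([effects[doses == d].mean() for d in uniq])
        ed50_0 = float(uniq[np.argmin(np.abs(means - emax0 / 2.0))])
        ed50_0 = float(np.clip(ed50_0, *ED50_BOUNDS))
        p0 = [min(emax0, EMAX_BOUNDS[1]), np.log10(ed50_0), 1.0]

    lb = [EMAX_BOUNDS[0], np.log10(ED50_BOUNDS[0]), HILL_BOUNDS[0]]
    ub = [EMAX_BOUNDS[1], np.log10(ED50_BOUNDS[1]), HILL_BOUNDS[1]]
    try:
        popt, pcov = optimize.curve_fit(
            _model, doses, effects, p0=p0, bounds=(lb, ub), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise UnidentifiableFitError(
            f"Hill fit failed for {data.drug_label}/{data.assay}: {exc}"
        ) from exc
    if not np.all(np.isfinite(pcov)):
        raise UnidentifiableFitError(
            f"rank-deficient Jacobian for {data.drug_label}/{data.assay}: "
            "parameters unidentifiable"
        )

    emax, l10, hill = popt
    ed50 = 10.0**l10
    # delta transform (emax, log10 ed50, hill) -> (emax, ed50, hill)
    J = np.diag([1.0, np.log(10.0) * ed50, 1.0])
    cov = J @ pcov @ J.T
    cov = (cov + cov.T) / 2.0
    ses = np.sqrt(np.diag(cov))
    n = doses.size
    return HillParams(
        emax=float(emax), ed50=float(ed50), hill=float(hill),
        se_emax=float(ses[0]), se_ed50=float(ses[1]), se_hill=float(ses[2]),
        cov=cov, n_animals=n, dof=max(n - 3, 0),
        label=f"{data.drug_label}/{data.assay}",
    )
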