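"""Unpaired t-test of the experimental vs predicted-additive ED50.

The experimental combination ED50 (from the fixed-ratio fit) and the
predicted-additive ED50 (from the dose-equivalence surface, SE by the
delta method) are compared with

    t = |pred - exp| / sqrt(se_exp^2 + se_pred^2),

with a two-sided p-value.  Degrees of freedom are, by default, the
Welch-Satterthwaite combination of the two estimates' dof; a normal
(z) approximation is available.  The verdict is directional: synergistic
only when the experimental ED50 is significantly *smaller* than predicted
(greater potency than additivity), antagonistic when significantly larger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ED50Estimate", "SynergyReport", "compare_ed50s"]


@dataclass(frozen=True)
class ED50Estimate:
    """An ED50 with its standard error and residual degrees of freedom."""

    ed50: float
    se: float
    dof: float

    def __post_init__(self) -> None:
        if self.ed50 <= 0 or self.se <= 0:
            raise ValueError("ED50 and SE must be positive")
        if self.dof < 1:
            raise ValueError(f"dof {self.dof} < 1: malformed estimate")


@dataclass(frozen=True)
class SynergyReport:
    """Outcome of the experimental-vs-predicted ED50 comparison."""

    assay: str
    exp_ed50: float
    exp_se: float
    pred_ed50: float
    pred_se: float
    t_stat: float
    dof: float
    p_value: float
    verdict: str  # synergistic | additive | antagonistic
    potency_ratio: float  # pred / exp: >1 means more potent than additive
    dof_convention: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def welch_satterthwaite(se1: float, dof1: float, se2: float, dof2: float) -> float:
    """Effective dof for the difference of two independent estimates."""
    num = (se1**2 + se2**2) ** 2
    den = se1**4 / dof1 + se2**4 / dof2
    return num / den


def compare_ed50s(
    exp: ED50Estimate,
    pred: ED50Estimate,
    alpha: float = 0.05,
    assay: str = "",
    dof_convention: str = "welch",
) -> SynergyReport:
    """Unpaired t-test of experimental vs predicted-additive ED50.

    Parameters
    ----------
    dof_convention:
        ``"welch"`` (default) uses the Welch-Satterthwaite combination of
        the two estimates' dof; ``"z"`` uses the normal approximation
        (infinite dof); ``"min"`` conservatively uses the smaller dof.

    The p-value is symmetric in the two estimates; the verdict is not:
    ``synergistic`` requires exp < pred with p < alpha, ``antagonistic``
    exp > pred with p < alpha, otherwise ``additive``.
    """
    se_diff = float(np.hypot(exp.se, pred.se))
    t = abs(pred.ed50 - exp.ed50) / se_diff
    if dof_convention == "welch":
        dof = welch_satterthwaite(exp.se, exp.dof, pred.se, pred.dof)
        p = 2.0 * stats.t.sf(t, dof)
    elif dof_convention == "z":
        dof = np.inf
        p = 2.0 * stats.norm.sf(t)
    elif dof_convention == "min":
        dof = min(exp.dof, pred.dof)
        p = 2.0 * stats.t.sf(t, dof)
    else:
        raise ValueError(f"unknown dof convention {dof_convention!r}")

    if p < alpha and exp.ed50 < pred.ed50:
        verdict = "synergistic"
    elif p < alpha and exp.ed50 > pred.ed50:
        verdict = "antagonistic"
    else:
        verdict = "additive"
    return SynergyReport(
        assay=assay,
        exp_ed50=exp.ed50,
        exp_se=exp.se,
        pred_ed50=pred.ed50,
        pred_se=pred.se,
        t_stat=float(t),
        dof=float(dof),
        p_value=float(min(p, 1.0)),
        verdict=verdict,
        potency_ratio=pred.ed50 / exp.ed50,
        dof_convention=dof_convention,
    )
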