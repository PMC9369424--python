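"""Loewe dose-equivalence additive surface for two drugs with unequal maxima.

Given Hill fits for drug A (the lower-maximum drug, parameters
``E_A, C_A, q``) and drug B (the higher-maximum drug, ``E_B, C_B, p``),
the predicted-additive effect of the dose pair (a, b) converts dose a of
drug A into its equi-effective dose of drug B and feeds the sum through
drug B's Hill curve:

    k(a)    = (E_B / E_A) * (1 + C_A^q / a^q) - 1
    b_eq(a) = C_B / k(a)^(1/p)
    E(a, b) = E_B * (b + b_eq)^p / (C_B^p + (b + b_eq)^p)

b_eq is the exact solution of the equi-effect condition
``hill(B, b_eq) = hill(A, a)``, which is what makes the construction a
Loewe additivity model: a drug combined with itself reproduces its own
curve at any ratio.  The predicted-additive ED50 on a fixed-ratio ray is
the total dose at which E(a, b) reaches half the composite maximum E_B;
its standard error is propagated from the two fits' parameter covariances
by the delta method (first-order Taylor expansion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dose_response import HillParams, hill_effect

__all__ = [
    "CombinationDesign",
    "AdditiveSurface",
    "PredictedED50",
    "k_factor",
    "b_equivalent",
    "additive_effect",
    "predicted_ed50",
    "predicted_ed50_se",
    "make_surface",
]


@dataclass(frozen=True)
class CombinationDesign:
    """Fixed-ratio ray: fractions of the total dose given as drug A and B.

    ``basis`` records whether the ratio is by weight or by mole; for
    structural isomers (equal molar mass) the two coincide.
    """

    frac_a: float = 0.5
    frac_b: float = 0.5
    basis: str = "weight"

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_a < 1.0 and 0.0 < self.frac_b < 1.0):
            raise ValueError("ray fractions must lie in (0, 1)")
        if abs(self.frac_a + self.frac_b - 1.0) > 1e-12:
            raise ValueError("ray fractions must sum to 1")
        if self.basis not in ("weight", "mole"):
            raise ValueError("basis must be 'weight' or 'mole'")


@dataclass(frozen=True)
class AdditiveSurface:
    """Eq.-style additive surface built from two single-drug Hill fits.

    ``params_a`` is the lower-maximum drug (E_A, C_A, q), ``params_b`` the
    higher-maximum one (E_B, C_B, p); the role rule E_B > E_A is enforced.
    ``printed_k`` switches the k factor to the (E_A/E_B) orientation found
    in some write-ups of the model; it violates the dose-equivalence
    identity and is provided only for comparison.
    """

    params_a: HillParams
    params_b: HillParams
    design: CombinationDesign = CombinationDesign()
    printed_k: bool = False
    check_roles: bool = True

    def __post_init__(self) -> None:
        # E_B >= E_A keeps k(a) positive for every finite a; equality (the
        # sham combination of a drug with itself) is mathematically sound.
        # check_roles=False admits an externally fixed role convention even
        # when sampling noise puts the fitted E_A slightly above E_B; k(a)
        # then goes negative only at doses far above the working range and
        # evaluation there raises.
        if self.check_roles and self.params_b.emax < self.params_a.emax:
            raise ValueError(
                "drug B must have the larger maximum "
                f"(E_B={self.params_b.emax} < E_A={self.params_a.emax}); "
                "use make_surface() for automatic role assignment"
            )


def make_surface(
    fit_x: HillParams,
    fit_y: HillParams,
    design: CombinationDesign = CombinationDesign(),
) -> AdditiveSurface:
    """Build a surface with automatic A/B role assignment by E_max.

    The drug with the larger maximal effect becomes drug B; an exact tie
    is broken by ED50 (the more potent drug becomes B).
    """
    if fit_x.emax == fit_y.emax:
        a, b = sorted((fit_x, fit_y), key=lambda p: p.ed50, reverse=True)
    else:
        a, b = sorted((fit_x, fit_y), key=lambda p: p.emax)
    return AdditiveSurface(params_a=a, params_b=b, design=design)


def k_factor(surface: AdditiveSurface, a: float) -> float:
    """Dose-equivalence factor k(a) for a dose ``a`` of drug A.

    k = (E_B/E_A) * (1 + C_A^q / a^q) - 1; strictly greater than
    E_B/E_A - 1 > 0 for any finite a, and -> infinity as a -> 0.
    """
    if a <= 0:
        return np.inf
    A, B = surface.params_a, surface.params_b
    ratio = (A.emax / B.emax) if surface.printed_k else (B.emax / A.emax)
    try:
        term = (A.ed50 / a) ** A.hill
    except OverflowError:  # vanishing a: no contribution from drug A
        return np.inf
    return ratio * (1.0 + term) - 1.0


def b_equivalent(surface: AdditiveSurface, a: float) -> float:
    """Equi-effective dose of drug B for a dose ``a`` of drug A.

    ``C_B / k(a)^(1/p)``; satisfies hill(B, b_eq(a)) = hill(A, a) exactly
    for every a > 0 (and 0 at a = 0).
    """
    if a < 0:
        raise ValueError("dose must be non-negative")
    if a == 0:
        return 0.0
    k = k_factor(surface, a)
    if k <= 0:
        raise ValueError(
            f"non-positive k factor ({k:.4g}) at a={a}: the printed-k "
            "orientation breaks down where drug A's effect exceeds "
            "E_A^2/E_B; use the dose-equivalence orientation"
        )
    return surface.params_b.ed50 / k ** (1.0 / surface.params_b.hill)


def additive_effect(surface: AdditiveSurface, a: float, b: float) -> float:
    """Predicted-additive effect (%MPE) of the dose pair (a, b).

    Reduces exactly to drug B's Hill curve at a = 0 and to drug A's effect
    at b = 0; returns 0 at a = b = 0 by convention.
    """
    if a < 0 or b < 0:
        raise ValueError("doses must be non-negative")
    if a == 0 and b == 0:
        return 0.0
    B = surface.params_b
    total = b + b_equivalent(surface, a)
    return B.emax * total**B.hill / (B.ed50**B.hill + total**B.hill)


@dataclass(frozen=True)
class PredictedED50:
    """Predicted-additive ED50 on a fixed-ratio ray, with delta-method SE."""

    ed50: float
    se: float
    effect_level: float  # %MPE at which the ED50 is defined (E_B / 2)

    def to_dict(self) -> dict:
        return {"ed50": self.ed50, "se": self.se, "effect_level": self.effect_level}


def _ray_ed50(surface: AdditiveSurface) -> float:
    fa, fb = surface.design.frac_a, surface.design.frac_b
    target = surface.params_b.emax / 2.0

    def f(total: float) -> float:
        return additive_effect(surface, fa * total, fb * total) - target

    # expand the bracket geometrically; with an externally fixed role
    # convention (E_B slightly below E_A) the surface is only defined up
    # to a finite dose, so probing a huge dose outright would raise
    lo, hi = 1e-9, max(surface.params_b.ed50, 1.0)
    while f(hi) < 0:
        hi *= 4.0
        if hi > 1e8:
            raise ValueError(
                "half the composite maximum is unreachable on the ray: "
                "inconsistent additive surface"
            )
    return optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)


def predicted_ed50(surface: AdditiveSurface, with_se: bool = True) -> PredictedED50:
    """Total dose on the ray at which the additive effect equals E_B / 2.

    Found by bracketed root-finding; the SE comes from
    :func:`predicted_ed50_se` (skipped, reported as 0, when ``with_se``
    is off -- useful inside resampling loops).
    """
    ed50 = _ray_ed50(surface)
    se = predicted_ed50_se(surface) if with_se else 0.0
    return PredictedED50(ed50=ed50, se=se, effect_level=surface.params_b.emax / 2.0)


def _surface_with_theta(surface: AdditiveSurface, theta: np.ndarray) -> AdditiveSurface:
    EA, CA, q, EB, CB, p = theta
    A = surface.params_a
    B = surface.params_b
    return AdditiveSurface(
        params_a=HillParams(emax=EA, ed50=CA, hill=q, cov=A.cov, dof=A.dof),
        params_b=HillParams(emax=EB, ed50=CB, hill=p, cov=B.cov, dof=B.dof),
        design=surface.design,
        printed_k=surface.printed_k,
        check_roles=False,  # gradient steps may nudge E_A past E_B
    )


def predicted_ed50_se(surface: AdditiveSurface, rel_step: float = 1e-5) -> float:
    """Delta-method SE of the predicted-additive ED50.

    First-order Taylor propagation through the implicit ED50 function of
    the six parameters theta = (E_A, C_A, q, E_B, C_B, p): the gradient g
    is computed by central differences (relative step ``rel_step``) and
    se^2 = g Sigma g^T with Sigma block-diagonal from the two fits'
    covariances -- the two drugs were fit on independent animal cohorts.
    """
    A, B = surface.params_a, surface.params_b
    Sigma = np.zeros((6, 6))
    Sigma[:3, :3] = _reorder_cov(A.cov)
    Sigma[3:, 3:] = _reorder_cov(B.cov)
    if np.linalg.eigvalsh(Sigma).min() < -1e-8:
        raise ValueError("non-PSD parameter covariance: upstream fit failure")
    theta = np.array([A.emax, A.ed50, A.hill, B.emax, B.ed50, B.hill])
    g = np.zeros(6)
    for i in range(6):
        h = rel_step * theta[i]
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (
            _ray_ed50(_surface_with_theta(surface, tp))
            - _ray_ed50(_surface_with_theta(surface, tm))
        ) / (2.0 * h)
    var = float(g @ Sigma @ g)
    return float(np.sqrt(max(var, 0.0)))


def _reorder_cov(cov: np.ndarray) -> np.ndarray:
    # HillParams cov is ordered (emax, ed50, hill); theta uses the same order
    return np.asarray(cov, dtype=float)


def ray_curve(surface: AdditiveSurface, total_doses) -> np.ndarray:
    """Predicted-additive effect along the ray at the given total doses."""
    fa, fb = surface.design.frac_a, surface.design.frac_b
    return np.array(
        [additive_effect(surface, fa * d, fb * d) for d in np.asarray(total_doses)]
    )


def combination_report(
    surface: AdditiveSurface,
    assay: str,
    experimental: HillParams | None = None,
) -> dict:
    """JSON-serializable summary of the predicted-additive analysis."""
    pred = predicted_ed50(surface)
    report = {
        "assay": assay,
        "ratio": [surface.design.frac_a, surface.design.frac_b],
        "predicted_ed50": pred.ed50,
        "predicted_se": pred.se,
        "effect_level": pred.effect_level,
        "drug_a": surface.params_a.label,
        "drug_b": surface.params_b.label,
    }
    if experimental is not None:
        report["experimental_ed50"] = experimental.ed50
        report["experimental_se"] = experimental.se_ed50
    return report
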