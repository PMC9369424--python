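"""Additivity isoboles in the (dose A, dose B) plane.

A non-linear additivity isobole at effect level L is the set of dose pairs
(a, b) whose predicted-additive effect equals L.  Under dose equivalence
it has the closed form

    b(a) = D_B(L) - b_eq(a),   D_B(L) = inverse_hill(drug B, L),

where D_B(L) is the dose of drug B alone producing the level and b_eq(a)
the B-equivalent of a; b is floored at 0.  Because b_eq saturates at the
B-dose equivalent of drug A's maximal effect, isoboles at levels above
E_A never meet the a-axis: no amount of the lower-efficacy drug alone can
produce the level.  The classical linear isobole (equal 100% maxima, unit
Hill slopes) is the straight line between the two single-drug ED50
intercepts and is included for comparison, as is a classifier that reads
a dose pair's position relative to an isobole as supra-additive (below),
additive (on) or sub-additive (above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .additive_model import AdditiveSurface, additive_effect, b_equivalent
from .dose_response import inverse_hill

__all__ = [
    "Isobole",
    "nonlinear_isobole",
    "linear_isobole",
    "classify_point",
    "DEFAULT_LEVELS",
]

#: effect-level family (20-50 %MPE)
DEFAULT_LEVELS = (20.0, 30.0, 40.0, 50.0)


@dataclass(frozen=True)
class Isobole:
    """A fixed-effect-level curve of dose pairs (a, b), both in nmol."""

    effect_level: float
    a: np.ndarray
    b: np.ndarray
    kind: str  # "nonlinear" | "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError("a and b grids must be parallel")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise ValueError("isobole doses must be non-negative")

    def b_at(self, a: float) -> float:
        """Interpolate the isobole's b-value at dose ``a`` of drug A."""
        if not self.a.min() <= a <= self.a.max():
            raise ValueError(
                f"a={a} outside the isobole's computed range "
                f"[{self.a.min()}, {self.a.max()}]: extrapolation refused"
            )
        return float(np.interp(a, self.a, self.b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a_nmol": self.a, "b_nmol": self.b, "level": self.effect_level}
        )


def nonlinear_isobole(
    surface: AdditiveSurface, level_percent: float, a_grid
) -> Isobole:
    """Dose-equivalence additivity isobole at ``level_percent`` %MPE.

    Every returned point with b > 0 satisfies
    ``additive_effect(a, b) == level_percent`` (closed loop); points where
    the formula goes negative are floored at 0, marking the region where
    drug A alone already exceeds the level.

    Raises
    ------
    ValueError
        If the level is at or above drug B's maximum (unreachable).
    """
    B = surface.params_b
    if not 0.0 < level_percent < B.emax:
        raise ValueError(
            f"effect level {level_percent} unreachable (must be in (0, {B.emax}))"
        )
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(a_grid < 0):
        raise ValueError("a_grid doses must be non-negative")
    d_b = inverse_hill(B, level_percent)
    b = np.array([max(d_b - b_equivalent(surface, a), 0.0) for a in a_grid])
    return Isobole(effect_level=level_percent, a=a_grid, b=b, kind="nonlinear")


def linear_isobole(ed50_a: float, ed50_b: float, a_grid) -> Isobole:
    """Classical 50%-effect-level isobole: the line through the ED50s.

    ``b = ed50_b * (1 - a / ed50_a)``, floored at 0; assumes both drugs
    have equal 100% maxima and unit Hill slopes.
    """
    if ed50_a <= 0 or ed50_b <= 0:
        raise ValueError("ED50s must be positive")
    a_grid = np.asarray(a_grid, dtype=float)
    b = np.maximum(ed50_b * (1.0 - a_grid / ed50_a), 0.0)
    return Isobole(effect_level=50.0, a=a_grid, b=b, kind="linear")


def classify_point(
    isobole: Isobole, a: float, b: float, rtol: float = 1e-6
) -> str:
    """Position of the dose pair (a, b) relative to an additivity isobole.

    Returns ``"supra-additive"`` when the point lies strictly below the
    curve at its a-coordinate (the combination achieves the level with
    less drug than additivity predicts), ``"additive"`` on the curve
    (within relative tolerance ``rtol``), ``"sub-additive"`` above.
    """
    if a < 0 or b < 0:
        raise ValueError("doses must be non-negative")
    b_curve = isobole.b_at(a)
    tol = rtol * max(abs(b_curve), 1.0)
    if abs(b - b_curve) <= tol:
        return "additive"
    return "supra-additive" if b < b_curve else "sub-additive"


def isobole_family(
    surface: AdditiveSurface,
    levels=DEFAULT_LEVELS,
    a_grid=None,
) -> list[Isobole]:
    """Non-linear isoboles at each level, on a shared a-grid.

    The default grid spans [0, 1.25 * C_A] -- the plotting region around
    the single-drug ED50 intercepts.
    """
    if a_grid is None:
        a_grid = np.linspace(0.0, 1.25 * surface.params_a.ed50, 101)
    return [nonlinear_isobole(surface, lv, a_grid) for lv in levels]
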