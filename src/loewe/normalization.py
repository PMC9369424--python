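"""Percent-maximum-possible-effect (%MPE) normalization of behavioral assays.

Raw behavioral read-outs from a neuropathic-pain study (von Frey paw
withdrawal thresholds, acetone response counts, rotarod and bar latencies)
are mapped onto a common 0-100 %MPE scale before dose-response analysis.
Each assay has its own normalization:

* mechanical PWT (threshold assay): ``100 * (post - pre) / (cutoff - pre)``
  with a filament cut-off of 6.84 g -- 100 % means the threshold was driven
  all the way to the cut-off;
* acetone and rotarod (reduction assays): ``100 * (pre - post) / pre`` --
  100 % means complete suppression of the pre-drug response;
* bar test (catalepsy): ``100 * (post - pre) / cutoff`` with a 120 s
  cut-off.

Open-field crossings are carried through raw (no %MPE) and negative scores
(worsening) are retained, not clipped; clipping is available as an option.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Assay",
    "RawMeasurement",
    "PWT_CUTOFF_G",
    "BAR_CUTOFF_S",
    "ROTAROD_CUTOFF_S",
    "mpe_threshold",
    "mpe_reduction",
    "mpe_bar",
    "mpe_for_assay",
    "invert_mpe_threshold",
    "invert_mpe_reduction",
    "invert_mpe_bar",
    "normalize_records",
    "read_records",
    "write_records",
    "RECORD_COLUMNS",
]

PWT_CUTOFF_G = 6.84
BAR_CUTOFF_S = 120.0
ROTAROD_CUTOFF_S = 300.0


class Assay(str, enum.Enum):
    """Behavioral assays of the chronic-constriction-injury study."""

    MECHANICAL_PWT = "mechanical_pwt"
    ACETONE = "acetone"
    ROTAROD = "rotarod"
    BAR = "bar"
    OPEN_FIELD = "open_field"


#: assays that get a %MPE normalization ("open_field" is analyzed raw)
NORMALIZED_ASSAYS = (Assay.MECHANICAL_PWT, Assay.ACETONE, Assay.ROTAROD, Assay.BAR)


@dataclass(frozen=True)
class RawMeasurement:
    """One pre/post-drug measurement for one animal in one assay.

    Units are grams for mechanical PWT, response counts for acetone and
    open field, and seconds for rotarod and bar latencies.
    """

    animal_id: str
    assay: Assay
    pre_drug: float
    post_drug: float
    timepoint_h: float = 1.0

    def __post_init__(self) -> None:
        if self.pre_drug < 0 or self.post_drug < 0:
            raise ValueError(
                f"negative measurement for animal {self.animal_id!r}: "
                f"pre={self.pre_drug}, post={self.post_drug}"
            )
        bound = {
            Assay.MECHANICAL_PWT: PWT_CUTOFF_G,
            Assay.BAR: BAR_CUTOFF_S,
            Assay.ROTAROD: ROTAROD_CUTOFF_S,
        }.get(Assay(self.assay))
        if bound is not None and (self.pre_drug > bound or self.post_drug > bound):
            raise ValueError(
                f"measurement above the {bound} cut-off for assay "
                f"{Assay(self.assay).value} (animal {self.animal_id!r})"
            )


def mpe_threshold(pre: float, post: float, cutoff: float = PWT_CUTOFF_G) -> float:
    """%MPE for a threshold assay: ``100 * (post - pre) / (cutoff - pre)``.

    ``pre`` is the (allodynic) pre-drug threshold, ``post`` the post-drug
    threshold, and ``cutoff`` the stiffest filament (6.84 g by default).
    Returns 100 exactly when the post-drug threshold reaches the cut-off.

    Raises
    ------
    ValueError
        If inputs are negative, exceed the cut-off, or ``pre >= cutoff``
        (a degenerate baseline with no room for improvement).
    """
    if pre < 0 or post < 0:
        raise ValueError("negative threshold measurement")
    if post > cutoff:
        raise ValueError(f"post-drug threshold {post} exceeds cut-off {cutoff}")
    if pre >= cutoff:
        raise ValueError(
            f"pre-drug threshold {pre} at or above cut-off {cutoff}: "
            "degenerate baseline, %MPE undefined"
        )
    return 100.0 * (post - pre) / (cutoff - pre)


def mpe_reduction(pre: float, post: float) -> float:
    """%MPE for a reduction assay: ``100 * (pre - post) / pre``.

    Used for acetone response counts and rotarod latencies; 100 % is full
    suppression of the pre-drug response.

    Raises
    ------
    ValueError
        If ``pre`` is zero (normalization undefined; flag the record
        upstream rather than coercing) or any input is negative.
    """
    if pre < 0 or post < 0:
        raise ValueError("negative measurement")
    if pre == 0:
        raise ValueError("pre-drug value of 0: reduction %MPE undefined")
    return 100.0 * (pre - post) / pre


def mpe_bar(pre: float, post: float, cutoff: float = BAR_CUTOFF_S) -> float:
    """%MPE for the bar (catalepsy) test: ``100 * (post - pre) / cutoff``.

    Raises
    ------
    ValueError
        If a latency is negative or exceeds the cut-off (120 s default).
    """
    if pre < 0 or post < 0:
        raise ValueError("negative latency")
    if pre > cutoff or post > cutoff:
        raise ValueError(f"latency above the {cutoff} s cut-off")
    return 100.0 * (post - pre) / cutoff


def invert_mpe_threshold(pre: float, mpe: float, cutoff: float = PWT_CUTOFF_G) -> float:
    """Post-drug threshold reproducing ``mpe`` given baseline ``pre``."""
    return pre + mpe / 100.0 * (cutoff - pre)


def invert_mpe_reduction(pre: float, mpe: float) -> float:
    """Post-drug value reproducing ``mpe`` given baseline ``pre``."""
    return pre * (1.0 - mpe / 100.0)


def invert_mpe_bar(pre: float, mpe: float, cutoff: float = BAR_CUTOFF_S) -> float:
    """Post-drug latency reproducing ``mpe`` given baseline ``pre``."""
    return pre + mpe / 100.0 * cutoff


_MPE_FUNCS = {
    Assay.MECHANICAL_PWT: lambda pre, post: mpe_threshold(pre, post),
    Assay.ACETONE: mpe_reduction,
    Assay.ROTAROD: mpe_reduction,
    Assay.BAR: lambda pre, post: mpe_bar(pre, post),
}


def mpe_for_assay(assay: Assay | str, pre: float, post: float,
                  clip: bool = False) -> float:
    """Dispatch to the assay's %MPE formula.

    Parameters
    ----------
    assay:
        One of the normalized assays; ``open_field`` is rejected (it is
        analyzed on the raw count scale).
    clip:
        If True, negative %MPE (behavioral worsening) is floored at 0.
        Off by default: signed scores are information-preserving and are
        what lets near-zero group means average out.
    """
    assay = Assay(assay)
    if assay not in _MPE_FUNCS:
        raise ValueError(f"assay {assay.value!r} is not %MPE-normalized")
    value = _MPE_FUNCS[assay](pre, post)
    return max(value, 0.0) if clip else value


# ---------------------------------------------------------------------------
# CSV dialect: per-animal records

RECORD_COLUMNS = [
    "animal_id",
    "group",
    "drug_a_dose_nmol",
    "drug_b_dose_nmol",
    "assay",
    "timepoint_h",
    "pre_drug",
    "post_drug",
]


def read_records(path) -> pd.DataFrame:
    """Read a per-animal records CSV (missing values as empty fields)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str, "assay": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} lacks columns: {missing}")
    return df


def write_records(df: pd.DataFrame, path) -> None:
    """Write a records table; NaN becomes an empty field."""
    df.to_csv(path, index=False)


def normalize_records(df: pd.DataFrame, clip: bool = False,
                      average_timepoints: bool = True) -> pd.DataFrame:
    """Append an ``mpe`` column to a records table.

    Duplicate rows for the same (animal, assay, timepoint) -- the behavioral
    protocol measures twice per time point -- are averaged on the raw scale
    before normalization.  When ``average_timepoints`` is set, the per-
    timepoint %MPE scores (1 h and 2 h post-drug) are then averaged into a
    single score per animal and assay; otherwise one row per timepoint is
    retained.  Open-field rows get ``mpe = NaN`` (analyzed raw).
    """
    keys = ["animal_id", "group", "drug_a_dose_nmol", "drug_b_dose_nmol",
            "assay", "timepoint_h"]
    df = (
        df.groupby(keys, dropna=False, as_index=False)[["pre_drug", "post_drug"]]
        .mean()
    )

    def _score(row):
        if Assay(row["assay"]) == Assay.OPEN_FIELD:
            return np.nan
        return mpe_for_assay(row["assay"], row["pre_drug"], row["post_drug"],
                             clip=clip)

    df = df.copy()
    df["mpe"] = df.apply(_score, axis=1)
    if average_timepoints:
        keys = [k for k in keys if k != "timepoint_h"]
        df = df.groupby(keys, dropna=False, as_index=False).agg(
            pre_drug=("pre_drug", "mean"),
            post_drug=("post_drug", "mean"),
            mpe=("mpe", "mean"),
        )
    return df
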