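"""Cleaning, end-trimming, and floor-mean gap imputation.

Cleaning marks every non-positive, non-finite, or out-of-range ([39, 400])
reading invalid.  Trimming removes invalid slots at both ends so the series
is anchored by in-bound readings.  Each interior run of invalid slots is then
filled by one of two integer-valued schemes:

``recursive_floor`` (default)
    Fill the run from its rightmost slot leftward; the value at in-run
    position n is ``floor((value at n+1 + left_anchor) / 2)``, seeded by the
    right anchor one past the run.  This decays geometrically toward the left
    anchor.

``linear_floor``
    Position n gets ``floor(left + (n+1) * (right - left) / (len + 1))`` —
    the floored straight line between the anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import floor

import numpy as np

from .cgm_io import CGMSeries, GLUCOSE_MAX, GLUCOSE_MIN
from .errors import ContractError, EmptySeriesError

IMPUTE_MODES = ("recursive_floor", "linear_floor")


@dataclass(frozen=True)
class GapRun:
    """A maximal run of consecutive invalid slots with its flanking readings."""

    start_index: int
    length: int
    left_anchor: float
    right_anchor: float

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("gap length must be >= 1")


def clean(series: CGMSeries) -> CGMSeries:
    """Mark missing, non-finite, non-positive, and out-of-range slots invalid."""
    out = series.copy()
    v = out.values
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(v) & (v > 0) & (v >= GLUCOSE_MIN) & (v <= GLUCOSE_MAX)
    out.valid = ok
    return out


def trim_ends(series: CGMSeries) -> CGMSeries:
    """Drop leading/trailing invalid slots so both ends are in-bound readings."""
    idx = np.flatnonzero(series.valid)
    if idx.size == 0:
        raise EmptySeriesError(f"{series.individual_id}: no valid slot to anchor on")
    lo, hi = idx[0], idx[-1] + 1
    return replace(
        series,
        t0=series.t0 + np.timedelta64(int(lo * series.dt * 60), "s"),
        values=series.values[lo:hi].copy(),
        valid=series.valid[lo:hi].copy(),
    )


def find_gaps(series: CGMSeries) -> list[GapRun]:
    """Enumerate maximal invalid runs, each with its flanking valid anchors.

    Requires a cleaned and trimmed series (first and last slots valid).
    """
    valid = series.valid
    if len(valid) and not (valid[0] and valid[-1]):
        raise ContractError("find_gaps requires a trimmed series (valid ends)")
    gaps: list[GapRun] = []
    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        gaps.append(
            GapRun(
                start_index=i,
                length=j - i,
                left_anchor=float(series.values[i - 1]),
                right_anchor=float(series.values[j]),
            )
        )
        i = j
    return gaps


def impute_gap(gap: GapRun, mode: str = "recursive_floor") -> list[float]:
    """Return ``gap.length`` imputed values between the anchors."""
    for name, a in (("left", gap.left_anchor), ("right", gap.right_anchor)):
        if not (GLUCOSE_MIN <= a <= GLUCOSE_MAX):
            raise ContractError(f"{name} anchor {a} outside [39, 400]")
    if mode not in IMPUTE_MODES:
        raise ContractError(f"unknown impute mode {mode!r}")
    L = gap.length
    left, right = gap.left_anchor, gap.right_anchor
    out = [0.0] * L
    if mode == "recursive_floor":
        nxt = right
        for n in range(L - 1, -1, -1):
            nxt = float(floor((nxt + left) / 2.0))
            out[n] = nxt
    else:
        step = (right - left) / (L + 1)
        for n in range(L):
            out[n] = float(floor(left + (n + 1) * step))
    return out


def impute(series: CGMSeries, mode: str = "recursive_floor") -> CGMSeries:
    """Fill every interior gap; previously valid slots are left bit-identical."""
    out = series.copy()
    for gap in find_gaps(series):
        vals = impute_gap(gap, mode)
        sl = slice(gap.start_index, gap.start_index + gap.length)
        out.values[sl] = vals
        out.valid[sl] = True
    return out


def preprocess(series: CGMSeries, mode: str = "recursive_floor") -> CGMSeries:
    """clean → trim_ends → impute, the full preparation chain."""
    return impute(trim_ends(clean(series)), mode)
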