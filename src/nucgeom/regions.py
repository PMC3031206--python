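"""Orientation of each dinucleotide step relative to the histone octamer.

Integral superhelix locations (SHL i) mark where the DNA major groove faces
the octamer; half-integral locations (SHL i.5) mark where the minor groove
faces it.  Around every SHL i the five basepairs at offsets i-2 .. i+2
belong to the major-groove-in region (III), the five at i+3 .. i+7 to the
minor-groove-in region (I), and the two steps straddling the boundaries
(i+2 -> i+3 and i+7 -> i+8) to the backbone-in region (II).  The layout is
periodic with the 10-bp helical repeat and symmetric about SHL 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["RegionLabel", "classify_region", "region_census"]

_MAJOR_PHASES = {8, 9, 0, 1}   # 5' basepair phase -> both bps within +-2 of SHL i
_MINOR_PHASES = {3, 4, 5, 6}   # both bps within the minor-groove block


@dataclass
class RegionLabel:
    region: str  # "I" (minor groove in), "II" (backbone in), "III" (major groove in)
    nearest_shl: float


def classify_region(offset5: int, offset3: int | None = None) -> RegionLabel:
    """Region of the step whose 5' basepair sits at dyad offset ``offset5``.

    ``offset3`` defaults to ``offset5 + 1`` and is accepted only as a sanity
    check that the two basepairs are consecutive.
    """
    if offset3 is not None and offset3 != offset5 + 1:
        raise ValueError("step basepairs must be consecutive in dyad offset")
    phase = offset5 % 10
    if phase in _MAJOR_PHASES:
        region = "III"
        nearest = float(round((offset5 + 0.5) / 10.0))
    elif phase in _MINOR_PHASES:
        region = "I"
        nearest = (10 * ((offset5 - 3) // 10) + 5) / 10.0
    else:  # phase 2 or 7: straddles a block boundary
        region = "II"
        lower = 10 * (offset5 // 10)
        # label with the block centre closest to the 5' basepair
        nearest = lower / 10.0 if phase == 2 else (lower + 5) / 10.0
    return RegionLabel(region=region, nearest_shl=nearest)


def region_census(
    steps: pd.DataFrame,
    value: str | None = None,
    by: tuple[str, ...] = ("step_class", "region", "combo"),
    min_n_for_sd: int = 5,
) -> pd.DataFrame:
    """Counts (and optionally mean/sd of ``value``) stratified per region.

    ``steps`` is a per-step table with at least the columns named in ``by``.
    The standard deviation is reported only for cells with n >= 5, matching
    the convention of the published summary tables; smaller cells carry NA.
    """
    grouped = steps.groupby(list(by), dropna=False, observed=True)
    out = grouped.size().rename("n").to_frame()
    if value is not None:
        out["mean"] = grouped[value].mean()
        sd = grouped[value].std(ddof=1)
        out["sd"] = sd.where(out["n"] >= min_n_for_sd)
    return out.reset_index()
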