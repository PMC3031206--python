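"""Kink detection via the 3-sigma rule against free B-DNA reference values.

A dinucleotide step is kinked when its tilt or roll deviates beyond three
standard deviations from the free B-DNA mean of that parameter.  The roll
reference values (mean 1.2 deg, 3-sigma bounds -14.7 and 17.1 deg) and the
slide references (mean 0.2 A, bounds -2.2 and 2.6 A) come from surveys of
high-resolution free B-DNA crystal structures; the tilt mean and sigma are
not distributed with this package and must be supplied explicitly when a
tilt-based census is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceDistributions",
    "KinkCall",
    "detect_kink",
    "kink_census",
    "compensation_check",
    "basepair_context",
]


@dataclass
class ReferenceDistributions:
    """Free B-DNA means and standard deviations for the kink criterion."""

    roll_mean: float = 1.2
    roll_sigma: float = 5.3
    slide_mean: float = 0.2
    slide_sigma: float = 0.8
    tilt_mean: float | None = None
    tilt_sigma: float | None = None
    source: str = "free B-DNA crystal-structure survey (roll/slide); tilt user-supplied"

    def __post_init__(self) -> None:
        for name in ("roll_sigma", "slide_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tilt_sigma is not None and self.tilt_sigma <= 0:
            raise ValueError("tilt_sigma must be positive")

    @property
    def has_tilt(self) -> bool:
        return self.tilt_mean is not None and self.tilt_sigma is not None


@dataclass
class KinkCall:
    tilt_out: bool
    roll_out: bool
    direction: str  # "minor", "major", "tilt-only", "none"
    roll_deviation: float = 0.0
    compensated: bool | None = None
    step_index: int | None = None

    @property
    def is_kink(self) -> bool:
        return self.tilt_out or self.roll_out


def detect_kink(
    tilt: float,
    roll: float,
    ref: ReferenceDistributions,
    require_tilt: bool = True,
) -> KinkCall:
    """Classify one step against the 3-sigma free B-DNA envelope.

    'Beyond 3-sigma' is strict: a roll exactly on the bound is not a kink.
    Kinks with roll below the lower bound bend into the minor groove
    ('minor'); above the upper bound into the major groove ('major'); a
    tilt-only excursion is direction 'tilt-only'.
    """
    if require_tilt and not ref.has_tilt:
        raise ValueError(
            "tilt reference constants are required: supply tilt_mean and "
            "tilt_sigma for the free B-DNA dataset (they are not bundled)"
        )
    roll_dev = roll - ref.roll_mean
    # tiny guard so values exactly on a printed 3-sigma bound are inside
    roll_out = abs(roll_dev) > 3.0 * ref.roll_sigma + 1e-9
    tilt_out = False
    if ref.has_tilt:
        tilt_out = abs(tilt - ref.tilt_mean) > 3.0 * ref.tilt_sigma + 1e-9
    if roll_out:
        direction = "minor" if roll_dev < 0 else "major"
    elif tilt_out:
        direction = "tilt-only"
    else:
        direction = "none"
    return KinkCall(
        tilt_out=tilt_out, roll_out=roll_out, direction=direction,
        roll_deviation=float(roll_dev),
    )


def detect_kinks_table(
    steps: pd.DataFrame, ref: ReferenceDistributions
) -> pd.DataFrame:
    """Vectorized kink flags for a per-step table (adds columns in a copy)."""
    out = steps.copy()
    roll_dev = out["roll"] - ref.roll_mean
    out["roll_out"] = roll_dev.abs() > 3.0 * ref.roll_sigma + 1e-9
    if ref.has_tilt:
        out["tilt_out"] = (out["tilt"] - ref.tilt_mean).abs() > 3.0 * ref.tilt_sigma + 1e-9
    else:
        out["tilt_out"] = False
    out["kink"] = out["roll_out"] | out["tilt_out"]
    out["kink_direction"] = np.select(
        [out["roll_out"] & (roll_dev < 0), out["roll_out"], out["tilt_out"]],
        ["minor", "major", "tilt-only"],
        default="none",
    )
    return out


def kink_census(
    flagged: pd.DataFrame,
    by: tuple[str, ...] = ("step_class", "region", "combo"),
    kink_and_slide: bool = False,
) -> pd.DataFrame:
    """Counts of kinked steps with within-cell percentages.

    ``flagged`` must carry the columns produced by :func:`detect_kinks_table`.
    With ``kink_and_slide`` the census is restricted to kinked steps that
    additionally have roll > 7 deg and slide < -1 A (the 'kink-and-slide'
    comparison filter).
    """
    work = flagged
    kink_col = work["kink"]
    if kink_and_slide:
        kink_col = kink_col & (work["roll"] > 7.0) & (work["slide"] < -1.0)
    work = work.assign(_kink=kink_col)
    grouped = work.groupby(list(by), dropna=False, observed=True)
    out = grouped.agg(n=("_kink", "size"), kinks=("_kink", "sum")).reset_index()
    out["percent"] = 100.0 * out["kinks"] / out["n"].where(out["n"] > 0)
    return out


def compensation_check(
    roll_values: "pd.Series | np.ndarray | list[float]",
    index: int,
    ref: ReferenceDistributions,
    window: int = 2,
) -> bool:
    """Is the roll kink at ``index`` compensated by an opposite neighbour?

    A roll-direction kink counts as compensated when some step within
    ``window`` positions carries a roll deviation of opposite sign whose
    magnitude is at least the kink's own deviation.  At a sequence edge only
    the available neighbours are examined.
    """
    rolls = np.asarray(roll_values, dtype=float)
    dev = rolls[index] - ref.roll_mean
    if dev == 0.0:
        return False
    lo = max(0, index - window)
    hi = min(len(rolls), index + window + 1)
    for j in range(lo, hi):
        if j == index:
            continue
        other = rolls[j] - ref.roll_mean
        if other * dev < 0.0 and abs(other) >= abs(dev):
            return True
    return False


def basepair_context(
    kinked_steps: pd.DataFrame,
    basepairs: pd.DataFrame,
    parameters: tuple[str, ...] = ("propeller", "buckle", "opening"),
    dataset_stats: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Flag whether each kinked step has a constituent basepair beyond
    1-sigma (and 2-sigma) of the dataset mean of the intra-pair parameters.

    ``basepairs`` is a per-basepair table indexed by (structure_id, offset);
    ``kinked_steps`` carries structure_id and offset5 of the 5' basepair.
    Dataset-wide per-parameter means/sigmas are computed from ``basepairs``
    unless supplied.
    """
    stats = dataset_stats or {
        p: (float(basepairs[p].mean()), float(basepairs[p].std(ddof=1)))
        for p in parameters
    }
    bp_idx = basepairs.set_index(["structure_id", "offset"])
    records = []
    for _, step in kinked_steps.iterrows():
        key5 = (step["structure_id"], step["offset5"])
        key3 = (step["structure_id"], step["offset5"] + 1)
        flag1 = flag2 = False
        for key in (key5, key3):
            if key not in bp_idx.index:
                continue
            row = bp_idx.loc[key]
            for p in parameters:
                mean, sigma = stats[p]
                value = row[p]
                if pd.isna(value) or sigma == 0:
                    continue
                dev = abs(value - mean)
                flag1 |= dev > sigma
                flag2 |= dev > 2.0 * sigma
        records.append(
            {
                "structure_id": step["structure_id"],
                "offset5": step["offset5"],
                "beyond_1sigma": flag1,
                "beyond_2sigma": flag2,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["structure_id", "offset5", "beyond_1sigma", "beyond_2sigma"]
    )
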