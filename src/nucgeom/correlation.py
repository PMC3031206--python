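"""Positional auto- and cross-correlation of per-step/per-basepair series.

Series are indexed by dyad offset so that structures of different length
(145-147 bp) can be compared: before cross-correlating, both series are
truncated to the common offset range and zero lag aligns SHL 0 with SHL 0.
The per-lag estimator is the Pearson correlation over the full overlap,
each segment centred by its own mean; a biased lag-windowed estimator
(normalisation by the full-series variance) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PositionalSeries", "autocorrelation", "crosscorrelation"]


@dataclass
class PositionalSeries:
    offsets: np.ndarray
    values: np.ndarray
    parameter_name: str = ""
    structure_id: str = ""

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets and values must have equal length")
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) == 1):
            raise ValueError("offsets must be contiguous")

    def restrict(self, lo: int, hi: int) -> "PositionalSeries":
        mask = (self.offsets >= lo) & (self.offsets <= hi)
        return PositionalSeries(
            self.offsets[mask], self.values[mask], self.parameter_name, self.structure_id
        )


def _pearson_lag(a: np.ndarray, b: np.ndarray, lag: int, biased: bool) -> float:
    """Correlation of (a_t, b_{t+lag}) over the full overlap."""
    if lag >= 0:
        x, y = a[: len(a) - lag or None], b[lag:]
    else:
        x, y = a[-lag:], b[: len(b) + lag or None]
    m = min(len(x), len(y))
    x, y = x[:m], y[:m]
    if m < 2:
        return np.nan
    if biased:
        xm, ym = a.mean(), b.mean()
        denom = len(a) * a.std() * b.std()
    else:
        xm, ym = x.mean(), y.mean()
        denom = np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
    if denom == 0:
        return np.nan
    return float(np.sum((x - xm) * (y - ym)) / denom)


def autocorrelation(
    s: PositionalSeries, max_lag: int, biased: bool = False
) -> np.ndarray:
    """Autocorrelation at lags 0..max_lag (lag 0 is exactly 1)."""
    if len(s.values) <= max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    return np.array(
        [_pearson_lag(s.values, s.values, k, biased) for k in range(max_lag + 1)]
    )


def crosscorrelation(
    a: PositionalSeries, b: PositionalSeries, max_lag: int, biased: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation at lags -max_lag..max_lag after SHL-0 alignment.

    Both series are truncated symmetrically to their common dyad-offset
    range; at zero lag equal offsets are compared.  Returns (lags, values).
    """
    lo = max(a.offsets.min(), b.offsets.min())
    hi = min(a.offsets.max(), b.offsets.max())
    if hi - lo + 1 < 2 * max_lag:
        raise ValueError("common offset range shorter than 2 * max_lag")
    ar = a.restrict(lo, hi)
    br = b.restrict(lo, hi)
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.array(
        [_pearson_lag(ar.values, br.values, int(k), biased) for k in lags]
    )
    return lags, values
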