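"""Pearson and time-lagged correlations between collective variables.

Lag convention: a positive lag tau compares x(t) against y(t + tau), i.e.
the second series is read later than the first; lags run from zero up to at
most half the series duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import CVSeries
from .cv import window_average

__all__ = ["LagCorrelation", "pearson", "lag_correlation", "window_scatter"]


@dataclass(frozen=True)
class LagCorrelation:
    """Correlation profile r(tau) for tau >= 0 (ns)."""

    lags: np.ndarray
    r: np.ndarray
    name_x: str = "x"
    name_y: str = "y"

    def __post_init__(self) -> None:
        if self.lags[0] != 0:
            raise ValueError("lag profile must include tau = 0")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def peak_lag(self) -> float:
        """Lag (ns) with the largest |r|."""
        return float(self.lags[np.argmax(np.abs(self.r))])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on zero variance instead of NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(x, y)[0])


def lag_correlation(x: CVSeries, y: CVSeries, max_lag: Optional[float] = None,
                    step: Optional[float] = None) -> LagCorrelation:
    """r(tau) = pearson(x(t), y(t + tau)) over the overlapping range.

    ``max_lag`` defaults to half the series duration; ``step`` defaults to
    one frame. Lags whose overlap would drop below 3 samples are truncated
    with a warning.
    """
    if abs(x.timestep - y.timestep) > 1e-12:
        raise ValueError("series must share a timestep")
    n = min(len(x), len(y))
    dt = x.timestep
    duration = (n - 1) * dt
    if max_lag is None:
        max_lag = duration / 2.0
    if max_lag > duration / 2.0 + 1e-12:
        raise ValueError("max_lag exceeds half the series duration")
    lag_frames = int(np.floor(max_lag / dt + 1e-9))
    step_frames = max(int(round((step or dt) / dt)), 1)
    if n - lag_frames < 3:
        lag_frames = max(n - 3, 0)
        warnings.warn("lag range truncated: overlap shorter than 3 samples")
    lags, rs = [], []
    for k in range(0, lag_frames + 1, step_frames):
        rs.append(pearson(x.values[: n - k], y.values[k:n]))
        lags.append(k * dt)
    return LagCorrelation(lags=np.asarray(lags), r=np.asarray(rs),
                          name_x=x.name, name_y=y.name)


def window_scatter(runs: Sequence[Tuple[CVSeries, CVSeries]],
                   last_ns: float = 2000.0):
    """Per-run trailing-window means of two CVs plus their pooled Pearson r.

    Mirrors the scatter-plot summaries built from the average of each run's
    last 2 us: every run contributes one (mean_x, mean_y) point; with >= 3
    runs the correlation across those points is returned, otherwise r is
    None.
    """
    points: List[Tuple[float, float]] = []
    for sx, sy in runs:
        mx, _ = window_average(sx, last_ns)
        my, _ = window_average(sy, last_ns)
        points.append((mx, my))
    r = None
    if len(points) >= 3:
        xs = np.array([p[0] for p in points])
        ys = np.array([p[1] for p in points])
        r = pearson(xs, ys)
    return points, r
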