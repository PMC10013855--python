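"""Four-state classification of Gs-alpha opening from the A161-E299 distance.

The opening coordinate is the geometric center-to-center distance between
residue A161 on the alpha-helical domain and E299 on the Ras-like domain.
Thresholds (defaults): fully open at >= 55 A, semi-open in [45, 55), semi-
closed in (35, 45), closed at <= 35 A. The boundary at 45 A is assigned to
semi-open, preserving the explicit >=/<= conventions at the outer bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Tuple

import numpy as np

from .core import CVSeries

__all__ = ["State", "StateThresholds", "StateSeries", "classify_state",
           "classify_series", "occupancy", "transition_counts"]


class State(str, Enum):
    CLOSED = "closed"
    SEMI_CLOSED = "semi_closed"
    SEMI_OPEN = "semi_open"
    OPEN = "open"


#: States ordered from most closed to most open.
STATE_ORDER = (State.CLOSED, State.SEMI_CLOSED, State.SEMI_OPEN, State.OPEN)


@dataclass(frozen=True)
class StateThresholds:
    """Distance cutoffs (Angstrom) separating the four opening states."""

    open_min: float = 55.0
    semiopen_min: float = 45.0
    semiclosed_min: float = 35.0

    def __post_init__(self) -> None:
        if not (self.open_min > self.semiopen_min > self.semiclosed_min > 0):
            raise ValueError("thresholds must satisfy open > semi-open > semi-closed > 0")


@dataclass(frozen=True)
class StateSeries:
    """Per-frame state labels plus the thresholds that produced them."""

    labels: Tuple[State, ...]
    thresholds: StateThresholds
    timestep: float = 1.0

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.timestep


def classify_state(distance: float, thresholds: StateThresholds = StateThresholds()) -> State:
    """Map one opening distance (Angstrom) to a state label."""
    if not distance > 0:
        raise ValueError(f"distance must be positive, got {distance}")
    if distance >= thresholds.open_min:
        return State.OPEN
    if distance >= thresholds.semiopen_min:
        return State.SEMI_OPEN
    if distance > thresholds.semiclosed_min:
        return State.SEMI_CLOSED
    return State.CLOSED


def classify_series(series: CVSeries,
                    thresholds: StateThresholds = StateThresholds()) -> StateSeries:
    """Element-wise classification of an opening-distance series."""
    if series.units != "A":
        raise ValueError("opening-distance series must be in Angstrom")
    labels = tuple(classify_state(float(v), thresholds) for v in series.values)
    return StateSeries(labels=labels, thresholds=thresholds, timestep=series.timestep)


def occupancy(states: StateSeries,
              window: Optional[Tuple[float, float]] = None) -> Dict[State, float]:
    """Fraction of frames in each state (sums to 1) over an optional
    inclusive time window ``(t_start_ns, t_end_ns)``."""
    labels = np.asarray([s.value for s in states.labels])
    if window is not None:
        t0, t1 = window
        mask = (states.times >= t0 - 1e-12) & (states.times <= t1 + 1e-12)
        labels = labels[mask]
    if labels.size == 0:
        raise ValueError("occupancy window contains no frames")
    return {s: float(np.mean(labels == s.value)) for s in STATE_ORDER
            if np.any(labels == s.value)}


def transition_counts(states: StateSeries) -> Dict[Tuple[State, State], int]:
    """Counts of frame-to-frame transitions between distinct states."""
    counts: Dict[Tuple[State, State], int] = {}
    for a, b in zip(states.labels[:-1], states.labels[1:]):
        if a is not b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts
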