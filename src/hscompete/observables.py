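"""Time-series observables and qualitative pattern classification.

The simulator's principal observable is the number of bound factors of each
class at each step.  Normal wound healing shows a sequential pattern — the
low-affinity stimulators peak and decline first, the medium-affinity
stabilizers next, and the high-affinity inhibitors accumulate and dominate
the late window.  Continuous tumor inflow of stimulators/stabilizers instead
keeps LA+MA occupancy high indefinitely, out-competing the inhibitors.
``classify_pattern`` operationalizes this visual distinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CLASS_ORDER

__all__ = [
    "BoundTimeSeries",
    "PatternVerdict",
    "SEQUENTIAL_RESOLVED",
    "UNRESOLVED_STIMULATION",
    "NO_SIGNAL",
    "peak_time",
    "average_replicates",
    "classify_pattern",
    "terminal_occupancy",
]

SEQUENTIAL_RESOLVED = "sequential_resolved"
UNRESOLVED_STIMULATION = "unresolved_stimulation"
NO_SIGNAL = "no_signal"


@dataclass(frozen=True, eq=False)
class BoundTimeSeries:
    """Per-class counts indexed by step t = 0..n_steps.

    ``counts`` has shape (n_timepoints, 3) with columns in ``CLASS_ORDER``.
    Raw replicates hold integers; replicate means may be fractional.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(CLASS_ORDER):
            raise ValueError(
                f"counts must have shape (n_timepoints, {len(CLASS_ORDER)}), "
                f"got {arr.shape}"
            )
        if arr.shape[0] == 0:
            raise ValueError("counts must contain at least one timepoint")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[0]

    def for_class(self, class_label: str) -> np.ndarray:
        return self.counts[:, CLASS_ORDER.index(class_label)]

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, columns=list(CLASS_ORDER), index=pd.RangeIndex(self.n_timepoints, name="step")
        )

    def equals(self, other: "BoundTimeSeries") -> bool:
        return self.counts.shape == other.counts.shape and np.array_equal(
            self.counts, other.counts
        )


@dataclass(frozen=True)
class PatternVerdict:
    """Outcome of the qualitative regime classification.

    ``label`` is one of ``sequential_resolved`` (wound-healing-like: ordered
    peaks, inhibitor-dominated tail), ``unresolved_stimulation`` (tumor-like:
    stimulator+stabilizer occupancy persists above the inhibitors'), or
    ``no_signal`` (nothing ever bound).  ``tail_means`` and ``peak_times``
    are the diagnostics the verdict was computed from.
    """

    label: str
    peak_times: dict[str, int]
    terminal_shares: dict[str, float]
    tail_means: dict[str, float]
    tail_fraction: float
    dominance_ratio: float


def peak_time(series: Sequence[float] | np.ndarray) -> int:
    """Index of the series maximum; ties break toward the earliest step."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("peak_time requires a non-empty 1-D series")
    return int(np.argmax(arr))


def average_replicates(results: Iterable[BoundTimeSeries]) -> BoundTimeSeries:
    """Pointwise arithmetic mean of replicate series, per class per step."""
    series = list(results)
    if not series:
        raise ValueError("average_replicates requires at least one series")
    shape = series[0].counts.shape
    for s in series[1:]:
        if s.counts.shape != shape:
            raise ValueError(
                f"series length mismatch: {s.counts.shape} vs {shape}"
            )
    return BoundTimeSeries(np.mean([s.counts for s in series], axis=0))


def _tail_window(n_timepoints: int, tail_fraction: float) -> int:
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError(f"tail_fraction must lie in (0, 1], got {tail_fraction}")
    return max(1, math.ceil(tail_fraction * n_timepoints))


def terminal_occupancy(
    summary: BoundTimeSeries, tail_fraction: float = 0.2
) -> dict[str, float]:
    """Per-class share of bound factors over the final window.

    The mean bound count of each class over the last ``tail_fraction`` of
    timepoints, normalized to shares summing to 1.  An all-zero window yields
    all-zero shares (the no-signal marker).
    """
    n = _tail_window(summary.n_timepoints, tail_fraction)
    tail_means = summary.counts[-n:].mean(axis=0)
    total = tail_means.sum()
    if total == 0:
        shares = np.zeros_like(tail_means)
    else:
        shares = tail_means / total
    return dict(zip(CLASS_ORDER, (float(s) for s in shares)))


def classify_pattern(
    summary: BoundTimeSeries,
    tail_fraction: float = 0.2,
    dominance_ratio: float = 1.0,
) -> PatternVerdict:
    """Classify an averaged bound series into a qualitative regime.

    ``sequential_resolved``: peaks ordered LA <= MA <= HA in time, and the
    inhibitors' (HA) mean bound count over the final ``tail_fraction`` of
    steps is at least ``dominance_ratio`` times the stimulator+stabilizer
    (LA+MA) mean over the same window.  ``unresolved_stimulation``: the tail
    LA+MA mean exceeds the tail HA mean.  ``no_signal``: nothing ever bound.
    Any residual case falls to whichever side of the dominance comparison it
    is nearer; the diagnostics are always reported.
    """
    n = _tail_window(summary.n_timepoints, tail_fraction)
    tail_means = summary.counts[-n:].mean(axis=0)
    peaks = {c: peak_time(summary.for_class(c)) for c in CLASS_ORDER}
    shares = terminal_occupancy(summary, tail_fraction)

    la_t, ma_t, ha_t = (float(v) for v in tail_means)
    stim_tail = la_t + ma_t

    if not summary.counts.any():
        label = NO_SIGNAL
    elif (
        peaks["LA"] <= peaks["MA"] <= peaks["HA"]
        and ha_t >= dominance_ratio * stim_tail
    ):
        label = SEQUENTIAL_RESOLVED
    elif stim_tail > ha_t:
        label = UNRESOLVED_STIMULATION
    else:
        # peaks out of order but inhibitors still dominate the tail (or vice
        # versa with a dominance_ratio != 1): fall to the nearer side of the
        # dominance comparison
        label = SEQUENTIAL_RESOLVED if ha_t >= stim_tail else UNRESOLVED_STIMULATION

    return PatternVerdict(
        label=label,
        peak_times=peaks,
        terminal_shares=shares,
        tail_means=dict(zip(CLASS_ORDER, (la_t, ma_t, ha_t))),
        tail_fraction=tail_fraction,
        dominance_ratio=dominance_ratio,
    )
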