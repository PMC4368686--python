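"""Core containers for beat-interval data.

An :class:`RRSeries` holds the inter-beat (RR) intervals of one recording
together with per-beat quality labels; an :class:`RRSegment` is a
contiguous, nominally 5-minute excerpt that has been through the
stationarity screen. Everything downstream (time-domain, spectral and
nonlinear HRV measures) consumes these two types.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

NORMAL = "normal"
ECTOPIC = "ectopic"
ARTIFACT = "artifact"

_VALID_LABELS = frozenset({NORMAL, ECTOPIC, ARTIFACT})


@dataclass
class RRSeries:
    """A beat-interval series.

    Parameters
    ----------
    intervals : array of float
        Inter-beat intervals in seconds; interval ``i`` separates beat
        ``i`` from beat ``i+1``.
    beat_times : array of float, optional
        Beat times in seconds from record start, strictly increasing and
        of length ``len(intervals) + 1``. Accumulated from zero when not
        given.
    beat_labels : array of str, optional
        One label per *interval* in ``{"normal", "ectopic", "artifact"}``.
    record_id : str
        Identifier carried into segment manifests and feature tables.
    record_start_clock : datetime.time, optional
        Wall-clock time of the first beat; enables daytime-window
        restriction during segment selection.
    """

    intervals: np.ndarray
    beat_times: np.ndarray | None = None
    beat_labels: np.ndarray | None = None
    record_id: str = "record"
    record_start_clock: _dt.time | None = None
    excess_removed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValueError("intervals must be a non-empty 1-D array")
        if np.any(self.intervals <= 0):
            raise ValueError("all intervals must be positive")
        if self.beat_times is None:
            self.beat_times = np.concatenate([[0.0], np.cumsum(self.intervals)])
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if self.beat_times.size != self.intervals.size + 1:
                raise ValueError("beat_times must have length len(intervals) + 1")
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat_times must be strictly increasing")
        if self.beat_labels is None:
            self.beat_labels = np.full(self.intervals.size, NORMAL, dtype=object)
        else:
            self.beat_labels = np.asarray(self.beat_labels, dtype=object)
            if self.beat_labels.size != self.intervals.size:
                raise ValueError("beat_labels must have one entry per interval")
            bad = set(self.beat_labels) - _VALID_LABELS
            if bad:
                raise ValueError(f"unknown beat labels: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    def good_mask(self) -> np.ndarray:
        """Intervals usable for feature computation (not artifact)."""
        return self.beat_labels != ARTIFACT

    def without_artifacts(self) -> "RRSeries":
        """Drop artifact-labelled intervals, keeping original beat times."""
        keep = self.good_mask()
        if keep.all():
            return self
        times = np.concatenate([self.beat_times[:-1][keep], [self.beat_times[-1]]])
        return replace(
            self,
            intervals=self.intervals[keep],
            beat_times=None if times.size != keep.sum() + 1 else times,
            beat_labels=self.beat_labels[keep],
        )


@dataclass
class StationarityResult:
    """Outcome of the surrogate-based stationarity test."""

    index_of_nonstationarity: float
    surrogate_threshold: float
    n_surrogates: int

    @property
    def is_stationary(self) -> bool:
        return self.index_of_nonstationarity <= self.surrogate_threshold


@dataclass
class RRSegment:
    """A stationarity-checked excerpt of an :class:`RRSeries`."""

    record_id: str
    start_time: float
    intervals: np.ndarray
    stationarity: StationarityResult | None = None
    non_stationary_fallback: bool = False
    beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.beat_times is None:
            self.beat_times = self.start_time + np.concatenate(
                [[0.0], np.cumsum(self.intervals)]
            )
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)

    @property
    def duration(self) -> float:
        return float(np.sum(self.intervals))

    def __len__(self) -> int:
        return int(self.intervals.size)
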