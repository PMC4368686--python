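"""RR preprocessing: artifact filtering, stationarity testing and
random daytime 5-minute segment selection.

The stationarity screen follows the surrogate scheme of Borgnat &
Flandrin: the interval series is resampled to a uniform grid, local
spectra over half-overlapping windows are compared to the global
spectrum by a scale-free spectral distance, and the variance of those
distances (the index of non-stationarity) is referred to the null
distribution obtained from phase-randomized surrogates, which are
stationary by construction. With 39 surrogates and a 95th-percentile
threshold the one-sided rank test has an exact nominal level of 2.5%.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import replace

import numpy as np
from scipy.interpolate import CubicSpline

from .series import ARTIFACT, RRSegment, RRSeries, StationarityResult

RESAMPLE_HZ = 4.0


def filter_artifacts(
    rr: RRSeries,
    min_rr: float = 0.3,
    max_rr: float = 2.0,
    local_dev: float = 0.2,
) -> RRSeries:
    """Label physiologically implausible intervals as artifact.

    An interval is an artifact if it lies outside ``[min_rr, max_rr]``
    seconds or deviates from the 5-beat running median by more than the
    fraction ``local_dev``. Ectopic-labelled beats that pass both checks
    keep their label; artifact supersedes. If more than 20% of beats are
    flagged the returned series carries ``excess_removed=True``.
    """
    x = rr.intervals
    if x.size < 11:
        raise ValueError("need at least 11 intervals to filter artifacts")
    med = _running_median(x, 5)
    bad = (x < min_rr) | (x > max_rr) | (np.abs(x - med) > local_dev * med)
    labels = rr.beat_labels.copy()
    labels[bad] = ARTIFACT
    out = replace(rr, beat_labels=labels)
    out.excess_removed = bool(bad.mean() > 0.20)
    return out


def _running_median(x: np.ndarray, w: int) -> np.ndarray:
    # centred window, shrunk at the edges; the tested value is excluded
    # so a lone outlier cannot mask itself
    n = x.size
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neigh = np.concatenate([x[lo:i], x[i + 1 : hi]])
        out[i] = np.median(neigh) if neigh.size else x[i]
    return out


def stationarity_test(
    intervals: np.ndarray,
    beat_times: np.ndarray | None = None,
    n_surrogates: int = 39,
    seed: int | np.random.Generator = 0,
) -> StationarityResult:
    """Surrogate test of second-order stationarity for an RR excerpt.

    The series is resampled to a 4 Hz grid by cubic interpolation;
    spectra of 50%-overlapping windows (a quarter of the segment each)
    are compared to the global spectrum, and the variance of the
    distances is the index of non-stationarity. The threshold is the
    95th percentile of the same index computed on phase-randomized
    surrogates.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 128:
        raise ValueError("stationarity test needs at least 128 intervals")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if beat_times is None:
        beat_times = np.concatenate([[0.0], np.cumsum(intervals)])
    y = _resample_uniform(intervals, beat_times)
    index = _nonstationarity_index(y)
    null = np.empty(n_surrogates)
    for k in range(n_surrogates):
        null[k] = _nonstationarity_index(_phase_randomize(y, rng))
    threshold = float(np.percentile(null, 95.0))
    return StationarityResult(
        index_of_nonstationarity=float(index),
        surrogate_threshold=threshold,
        n_surrogates=n_surrogates,
    )


def _resample_uniform(intervals: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    t = beat_times[1:]
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    return CubicSpline(t, intervals)(grid)


def _nonstationarity_index(y: np.ndarray) -> float:
    n = y.size
    win = max(32, n // 4)
    hop = win // 2
    starts = range(0, n - win + 1, hop)
    window = np.hanning(win)
    specs = []
    for s in starts:
        seg = y[s : s + win]
        seg = (seg - seg.mean()) * window
        p = np.abs(np.fft.rfft(seg)) ** 2
        specs.append(p[1:])  # drop DC so the distance is mean-free
    specs = np.asarray(specs)
    global_spec = specs.mean(axis=0)
    dists = [_spectral_distance(p, global_spec) for p in specs]
    return float(np.var(dists))


def _spectral_distance(p: np.ndarray, q: np.ndarray) -> float:
    # symmetric KL between unit-mass spectra: invariant to a common
    # rescaling of the series, as required for a scale-free verdict
    eps = 1e-12
    p = p / (p.sum() + eps) + eps
    q = q / (q.sum() + eps) + eps
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def _phase_randomize(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(y - y.mean())
    phases = rng.uniform(0, 2 * np.pi, spec.size)
    phases[0] = 0.0
    if y.size % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=y.size) + y.mean()


def select_stationary_segment(
    rr: RRSeries,
    duration: float = 300.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 50,
    n_surrogates: int = 39,
    daytime: tuple[_dt.time, _dt.time] | None = (_dt.time(8), _dt.time(20)),
) -> RRSegment:
    """Randomly select a stationary excerpt of ``duration`` seconds.

    Candidate start times are drawn uniformly over the record (restricted
    to the daytime window when the record carries a wall-clock start).
    The first candidate passing :func:`stationarity_test` is returned;
    after ``max_tries`` failures the candidate with the lowest index of
    non-stationarity is returned flagged ``non_stationary_fallback``.
    Artifact-labelled intervals are never included.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    clean = rr.without_artifacts()
    if clean.duration <= duration:
        raise ValueError(
            f"record {rr.record_id}: duration {clean.duration:.0f}s "
            f"not longer than requested segment ({duration:.0f}s)"
        )
    lo, hi = _eligible_start_range(clean, duration, daytime)
    best: tuple[float, RRSegment] | None = None
    for _ in range(max_tries):
        start = rng.uniform(lo, hi)
        seg_int, seg_t0 = _cut(clean, start, duration)
        if seg_int.size < 128:
            continue
        res = stationarity_test(seg_int, seed=rng, n_surrogates=n_surrogates)
        seg = RRSegment(
            record_id=clean.record_id,
            start_time=seg_t0,
            intervals=seg_int,
            stationarity=res,
        )
        if res.is_stationary:
            return seg
        margin = res.index_of_nonstationarity - res.surrogate_threshold
        if best is None or margin < best[0]:
            best = (margin, seg)
    if best is None:
        raise ValueError(f"record {rr.record_id}: no candidate segment had enough beats")
    seg = best[1]
    seg.non_stationary_fallback = True
    return seg


def _eligible_start_range(
    rr: RRSeries, duration: float, daytime: tuple[_dt.time, _dt.time] | None
) -> tuple[float, float]:
    lo, hi = 0.0, rr.duration - duration
    if daytime is not None and rr.record_start_clock is not None:
        t0 = (
            rr.record_start_clock.hour * 3600
            + rr.record_start_clock.minute * 60
            + rr.record_start_clock.second
        )
        day_lo = daytime[0].hour * 3600 + daytime[0].minute * 60 - t0
        day_hi = daytime[1].hour * 3600 + daytime[1].minute * 60 - t0 - duration
        if day_hi < day_lo:  # window wraps past midnight relative to start
            day_lo, day_hi = lo, hi
        lo, hi = max(lo, day_lo), min(hi, max(day_hi, lo + 1e-9))
        if hi <= lo:
            lo, hi = 0.0, rr.duration - duration
    return lo, hi


def _cut(rr: RRSeries, start: float, duration: float) -> tuple[np.ndarray, float]:
    """Intervals accumulating to at least ``duration`` from ``start``."""
    t = rr.beat_times
    i0 = int(np.searchsorted(t, start, side="left"))
    if i0 >= len(rr):
        i0 = len(rr) - 1
    acc = 0.0
    j = i0
    while j < len(rr) and acc < duration:
        acc += rr.intervals[j]
        j += 1
    return rr.intervals[i0:j], float(t[i0])
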