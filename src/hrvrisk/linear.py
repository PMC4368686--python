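"""Time-domain and frequency-domain HRV measures.

Time domain: AVNN, SDNN, RMSSD, NN50, pNN50, the HRV triangular index
(interval count over the modal bin count of a histogram with 1/128 s
bins) and TINN (base width of the least-squares triangle fitted to that
histogram, apex fixed at the mode).

Frequency domain: a Lomb–Scargle periodogram of the beat-time-indexed
interval series — no resampling, which is the point of using Lomb on
unevenly sampled RR data — renormalized so the integral of the density
over (0, f_max] equals the sample variance of the intervals, then band
powers over VLF (0–0.04 Hz), LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz),
their relative and normalized-unit forms, the LF/HF ratio and per-band
peak frequencies. All powers are in s² (densities s²/Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .series import RRSegment

HIST_BIN = 1.0 / 128.0  # seconds; conventional discrete scale for HRVTi/TINN

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class PowerSpectrum:
    """One-sided PSD of the interval series, density in s²/Hz."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be increasing")
        if np.any(self.power < 0):
            raise ValueError("power density must be non-negative")


def time_domain_features(segment: RRSegment | np.ndarray) -> dict[str, float]:
    x = _intervals(segment)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.diff(x)
    nn50 = int(np.sum(np.abs(diffs) > 0.050))
    hrvti, tinn = _triangular_measures(x)
    return {
        "AVNN": float(np.mean(x)),
        "SDNN": float(np.std(x, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(diffs**2))),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / diffs.size,
        "HRVTi": hrvti,
        "TINN": tinn,
    }


def _histogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # bins aligned on multiples of 1/128 s
    lo = np.floor(x.min() / HIST_BIN)
    hi = np.floor(x.max() / HIST_BIN) + 1
    edges = np.arange(lo, hi + 1) * HIST_BIN
    counts, _ = np.histogram(x, bins=edges)
    return counts.astype(float), edges


def _triangular_measures(x: np.ndarray) -> tuple[float, float]:
    counts, edges = _histogram(x)
    peak = counts.max()
    hrvti = x.size / peak
    tinn = _tinn(counts, edges)
    return float(hrvti), float(tinn)


def _tinn(counts: np.ndarray, edges: np.ndarray) -> float:
    """Base width of the best-fit triangle (least squares, apex at mode)."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(counts))
    peak = counts[k]
    if counts.size == 1:
        return HIST_BIN
    best = (np.inf, HIST_BIN)
    for i in range(0, k + 1):  # left foot bin
        for j in range(k, counts.size):  # right foot bin
            tri = np.zeros_like(counts)
            if k > i:
                left = np.arange(i, k + 1)
                tri[left] = peak * (centers[left] - centers[i]) / (centers[k] - centers[i])
            if j > k:
                right = np.arange(k, j + 1)
                tri[right] = peak * (centers[j] - centers[right]) / (centers[j] - centers[k])
            tri[k] = peak
            err = float(np.sum((counts - tri) ** 2))
            width = centers[j] - centers[i] + HIST_BIN
            if err < best[0] - 1e-12:
                best = (err, width)
    return best[1]


def lomb_psd(
    segment: RRSegment | np.ndarray,
    beat_times: np.ndarray | None = None,
    f_max: float = 0.4,
    oversample: int = 4,
) -> PowerSpectrum:
    """Parseval-normalized Lomb–Scargle PSD of an interval series.

    The density is rescaled so that its trapezoidal integral over
    (0, f_max] equals the n−1 sample variance of the intervals; a
    constant series therefore yields an all-zero spectrum.
    """
    x = _intervals(segment)
    if x.size < 16:
        raise ValueError("need at least 16 intervals for a spectrum")
    if beat_times is None:
        if isinstance(segment, RRSegment):
            beat_times = segment.beat_times[1:]
        else:
            beat_times = np.cumsum(x)
    t = np.asarray(beat_times, dtype=float)
    span = t[-1] - t[0]
    df = 1.0 / (span * oversample)
    freqs = np.arange(df, f_max + 0.5 * df, df)
    var = float(np.var(x, ddof=1))
    if np.ptp(x) == 0.0 or var == 0.0:
        return PowerSpectrum(freqs, np.zeros_like(freqs))
    xc = x - x.mean()
    raw = lombscargle(t, xc, 2.0 * np.pi * freqs)
    area = np.trapezoid(raw, freqs)
    power = raw * (var / area) if area > 0 else np.zeros_like(raw)
    return PowerSpectrum(freqs, power)


def frequency_domain_features(spectrum: PowerSpectrum) -> dict[str, float]:
    f, p = spectrum.frequencies, spectrum.power
    vlf = _band_power(f, p, *VLF_BAND)
    lf = _band_power(f, p, *LF_BAND)
    hf = _band_power(f, p, *HF_BAND)
    tp = vlf + lf + hf
    out: dict[str, float] = {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "TP": tp,
        "VLF_peak": _band_peak(f, p, *VLF_BAND),
        "LF_peak": _band_peak(f, p, *LF_BAND),
        "HF_peak": _band_peak(f, p, *HF_BAND),
    }
    if tp > 0:
        out["VLF_pct"] = 100.0 * vlf / tp
        out["LF_pct"] = 100.0 * lf / tp
        out["HF_pct"] = 100.0 * hf / tp
    else:
        out["VLF_pct"] = out["LF_pct"] = out["HF_pct"] = np.nan
    denom = tp - vlf
    if denom > 0:
        out["LF_nu"] = 100.0 * lf / denom
        out["HF_nu"] = 100.0 * hf / denom
    else:
        out["LF_nu"] = out["HF_nu"] = np.nan
    out["LF_HF"] = lf / hf if hf > 0 else np.nan
    return out


def _band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over the half-open band (lo, hi]."""
    inside = (f > lo) & (f <= hi)
    if not inside.any():
        return 0.0
    # include interpolated density at the exact band edges so adjacent
    # bands tile the axis without double counting
    grid = np.unique(np.concatenate([[lo, hi], f[inside]]))
    grid = grid[(grid >= max(lo, f[0])) & (grid <= min(hi, f[-1]))]
    if grid.size < 2:
        return 0.0
    dens = np.interp(grid, f, p)
    return float(np.trapezoid(dens, grid))


def _band_peak(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    inside = (f > lo) & (f <= hi)
    if not inside.any():
        return np.nan
    fi, pi = f[inside], p[inside]
    return float(fi[np.argmax(pi)])


def _intervals(segment: RRSegment | np.ndarray) -> np.ndarray:
    if isinstance(segment, RRSegment):
        return segment.intervals
    return np.asarray(segment, dtype=float)
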