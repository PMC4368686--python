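"""Nonlinear HRV measures.

Poincaré SD1/SD2, approximate and sample entropy (Pincus / Richman–
Moorman definitions, Chebyshev distance), Grassberger–Procaccia
correlation dimension, detrended fluctuation analysis (Alpha1 over box
sizes 4–16 beats, Alpha2 over 16–64) and recurrence quantification
(REC, DET, L_mean, L_max, Shannon entropy of the diagonal-line-length
distribution, and divergence 1/L_max).

Tolerance conventions: entropies use r = 0.2·SDNN; the recurrence
radius is sqrt(m)·SDNN, which keeps the recurrence rate comparable
across embedding dimensions since embedded distances grow like sqrt(m).
All logarithms are natural. Tying every tolerance to SDNN makes each
measure invariant to adding a constant to all intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EmbeddingConfig:
    """Phase-space embedding parameters for CD and recurrence analysis."""

    m: int = 10
    tau: int = 1
    r_sdnn_factor: float | None = None  # None → sqrt(m)·SDNN for RQA
    theiler: int = 1
    l_min: int = 2

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1 or self.l_min < 2 or self.theiler < 0:
            raise ValueError("invalid embedding configuration")

    def radius(self, sdnn: float) -> float:
        factor = np.sqrt(self.m) if self.r_sdnn_factor is None else self.r_sdnn_factor
        return float(factor * sdnn)


def poincare_sd(intervals: np.ndarray) -> tuple[float, float]:
    """SD1/SD2 of the lag-one Poincaré plot (n−1 estimators)."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals for a Poincaré plot")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((a - b) / np.sqrt(2.0), ddof=1))
    sd2 = float(np.std((a + b) / np.sqrt(2.0), ddof=1))
    return sd1, sd2


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for requested embedding")
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]


def approximate_entropy(intervals: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r): Φ_m − Φ_{m+1} with self-matches included (Pincus)."""
    x = np.asarray(intervals, dtype=float)
    if x.size < m + 2:
        raise ValueError("series too short for ApEn")
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        emb = _embed(x, mm, 1)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = np.mean(d <= r, axis=1)  # self-match included
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(intervals: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = −ln(A/B), self-matches excluded (Richman–Moorman).

    Returns NaN when no template pair matches at length m or m+1.
    Template counts use the standard construction with N−m templates at
    both lengths so A and B are comparable.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < m + 2:
        raise ValueError("series too short for SampEn")
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0:
        return np.nan

    def count(mm: int) -> int:
        emb = _embed(x, mm, 1)[: x.size - m]  # N−m templates at both lengths
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        iu = np.triu_indices(emb.shape[0], k=1)
        return int(np.sum(d[iu] <= r))

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def correlation_dimension(
    intervals: np.ndarray,
    config: EmbeddingConfig | None = None,
    n_radii: int = 24,
) -> float:
    """Grassberger–Procaccia correlation dimension of the embedded series."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 intervals for CD")
    cfg = config or EmbeddingConfig(m=10, tau=1)
    pts = _embed(x, cfg.m, cfg.tau)
    return correlation_dimension_points(pts, theiler=cfg.theiler, n_radii=n_radii)


def correlation_dimension_points(
    points: np.ndarray, theiler: int = 1, n_radii: int = 24
) -> float:
    """CD of an arbitrary point cloud: slope of log C(r) vs log r over the
    most stable scaling region (minimum-variance window of 5 local slopes)."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    d = np.sqrt(np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2))
    i, j = np.triu_indices(n, k=theiler + 1)
    dist = d[i, j]
    dist = dist[dist > 0]
    if dist.size < 10:
        return np.nan
    r_lo, r_hi = np.percentile(dist, [2.0, 98.0])
    if r_lo <= 0 or r_hi <= r_lo:
        return np.nan
    radii = np.logspace(np.log10(r_lo), np.log10(r_hi), n_radii)
    c = np.searchsorted(np.sort(dist), radii, side="right") / dist.size
    # keep the informative part of the correlation sum: below ~1% the
    # counts are too sparse, above ~50% the sum saturates
    ok = (c >= 0.01) & (c <= 0.5)
    if ok.sum() < 6:
        ok = c > 0
    logr, logc = np.log(radii[ok]), np.log(c[ok])
    if logr.size < 6:
        return np.nan
    slopes = np.diff(logc) / np.diff(logr)
    w = 5
    if slopes.size < w:
        return float(np.polyfit(logr, logc, 1)[0])
    var = np.array([np.var(slopes[k : k + w]) for k in range(slopes.size - w + 1)])
    k = int(np.argmin(var))
    sel = slice(k, k + w + 1)
    return float(np.polyfit(logr[sel], logc[sel], 1)[0])


def dfa(
    intervals: np.ndarray,
    short_scales: tuple[int, int] = (4, 16),
    long_scales: tuple[int, int] = (16, 64),
) -> tuple[float, float]:
    """First-order DFA exponents (Alpha1, Alpha2).

    The mean-subtracted series is integrated; for each box size the RMS
    residual around per-box linear fits is computed over non-overlapping
    boxes (partial final box discarded); each alpha is the log–log slope
    over its scale band. An alpha whose band cannot be populated (series
    too short) is returned as NaN.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 intervals for DFA")

    def alpha(lo: int, hi: int) -> float:
        ns, fs = dfa_profile(x, lo, hi)
        ok = np.isfinite(fs) & (fs > 0)
        if ok.sum() < 3:
            return np.nan
        return float(np.polyfit(np.log(ns[ok]), np.log(fs[ok]), 1)[0])

    a1 = alpha(*short_scales)
    a2 = alpha(*long_scales) if x.size >= 130 else np.nan
    return a1, a2


def dfa_profile(
    intervals: np.ndarray, lo: int, hi: int, n_scales: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Box sizes and RMS fluctuations F(n) of first-order DFA."""
    x = np.asarray(intervals, dtype=float)
    y = np.cumsum(x - x.mean())

    def fluct(n: int) -> float:
        k = y.size // n
        if k < 2:
            return np.nan
        seg = y[: k * n].reshape(k, n)
        t = np.arange(n)
        # per-box least-squares line via closed form
        tm, t2 = t.mean(), (t**2).mean()
        sm = seg.mean(axis=1)
        stm = (seg * t).mean(axis=1)
        slope = (stm - sm * tm) / (t2 - tm**2)
        inter = sm - slope * tm
        resid = seg - (slope[:, None] * t + inter[:, None])
        return float(np.sqrt(np.mean(resid**2)))

    ns = np.unique(np.round(np.geomspace(lo, hi, n_scales)).astype(int))
    fs = np.array([fluct(n) for n in ns])
    # finite-size debiasing: for first-order DFA on white noise
    # E[F²(n)] = σ²(n²−4)/(15n), not ∝ n, which inflates the slope at
    # small boxes; dividing by sqrt(1 − 4/n²) restores F ∝ n^0.5 there
    fs = fs / np.sqrt(1.0 - 4.0 / ns.astype(float) ** 2)
    return ns, fs


def recurrence_quantification(
    intervals: np.ndarray,
    config: EmbeddingConfig | None = None,
    r: float | None = None,
) -> dict[str, float]:
    """Recurrence-plot measures of the embedded interval series.

    Returns REC (%), DET (%), L_mean, L_max (beats), ShanEn (nats) and
    DIV = 1/L_max. The recurrence matrix uses Euclidean distance with a
    Theiler exclusion band around the main diagonal; line statistics are
    taken over diagonals of the upper triangle with length ≥ l_min.
    """
    x = np.asarray(intervals, dtype=float)
    cfg = config or EmbeddingConfig(m=10, tau=1)
    if x.size < cfg.m * cfg.tau + 10:
        raise ValueError("series too short for recurrence analysis")
    if r is None:
        r = cfg.radius(np.std(x, ddof=1))
    pts = _embed(x, cfg.m, cfg.tau)
    n = pts.shape[0]
    d = np.sqrt(np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2))
    rec = d <= r
    lengths: list[int] = []
    n_recurrent = 0
    for off in range(cfg.theiler + 1, n):
        diag = np.diagonal(rec, offset=off)
        n_recurrent += int(diag.sum())
        lengths.extend(_run_lengths(diag))
    eligible = sum(n - off for off in range(cfg.theiler + 1, n))
    out: dict[str, float] = {}
    out["REC"] = 100.0 * n_recurrent / eligible if eligible else np.nan
    lines = [L for L in lengths if L >= cfg.l_min]
    if n_recurrent == 0:
        out.update(DET=np.nan, L_mean=np.nan, L_max=np.nan, ShanEn=np.nan, DIV=np.nan)
        return out
    pts_on_lines = sum(lines)
    out["DET"] = 100.0 * pts_on_lines / n_recurrent
    if lines:
        out["L_mean"] = float(np.mean(lines))
        out["L_max"] = float(max(lines))
        out["DIV"] = 1.0 / out["L_max"]
        _, counts = np.unique(lines, return_counts=True)
        p = counts / counts.sum()
        out["ShanEn"] = float(-np.sum(p * np.log(p)))
    else:
        out.update(L_mean=np.nan, L_max=np.nan, ShanEn=np.nan, DIV=np.nan)
    return out


def _run_lengths(mask: np.ndarray) -> list[int]:
    if mask.size == 0:
        return []
    padded = np.concatenate([[0], mask.astype(int), [0]])
    changes = np.diff(padded)
    starts = np.flatnonzero(changes == 1)
    ends = np.flatnonzero(changes == -1)
    return list(ends - starts)
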