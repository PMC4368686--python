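import math

import numpy as np
import pytest

from hrvrisk.nonlinear import (
    EmbeddingConfig,
    approximate_entropy,
    correlation_dimension,
    correlation_dimension_points,
    dfa,
    dfa_profile,
    poincare_sd,
    recurrence_quantification,
    sample_entropy,
)

# ------------------------------------------------------------------ oracles


def apen_bruteforce(x, m, r):
    """Double-loop Pincus ApEn with self-matches included."""
    def phi(mm):
        templates = [x[i : i + mm] for i in range(len(x) - mm + 1)]
        logs = []
        for a in templates:
            c = sum(
                max(abs(u - v) for u, v in zip(a, b)) <= r for b in templates
            )
            logs.append(math.log(c / len(templates)))
        return sum(logs) / len(logs)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r):
    """Double-loop SampEn, self-matches excluded, N−m templates."""
    def count(mm):
        templates = [x[i : i + mm] for i in range(len(x) - m)]
        hits = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(u - v) for u, v in zip(templates[i], templates[j])) <= r:
                    hits += 1
        return hits

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def rqa_bruteforce(x, m, tau, r, theiler, l_min):
    """O(n^2) recurrence-matrix scan of the upper triangle."""
    n = len(x) - (m - 1) * tau
    emb = [[x[i + k * tau] for k in range(m)] for i in range(n)]
    rec = [
        [
            math.dist(emb[i], emb[j]) <= r
            for j in range(n)
        ]
        for i in range(n)
    ]
    n_rec, eligible, lengths = 0, 0, []
    for off in range(theiler + 1, n):
        run = 0
        for i in range(n - off):
            eligible += 1
            if rec[i][i + off]:
                n_rec += 1
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    out = {"REC": 100.0 * n_rec / eligible}
    lines = [L for L in lengths if L >= l_min]
    if n_rec == 0:
        return out
    out["DET"] = 100.0 * sum(lines) / n_rec
    if lines:
        out["L_mean"] = sum(lines) / len(lines)
        out["L_max"] = max(lines)
        out["DIV"] = 1.0 / max(lines)
        counts = {}
        for L in lines:
            counts[L] = counts.get(L, 0) + 1
        p = [c / len(lines) for c in counts.values()]
        out["ShanEn"] = -sum(q * math.log(q) for q in p)
    return out


# ------------------------------------------------------------------- tests


class TestPoincare:
    def test_alternating_pattern_hand_values(self):
        x = np.tile([0.8, 1.0], 50)
        sd1, sd2 = poincare_sd(x)
        assert sd2 == pytest.approx(0.0, abs=1e-15)
        # 99 successive differences: 50 of −0.2/√2, 49 of +0.2/√2;
        # hand-computed sample SD = sqrt((1.98 − 99·mean²)/98) = 0.142133
        assert sd1 == pytest.approx(0.14213381, abs=1e-6)

    def test_constant_series(self):
        sd1, sd2 = poincare_sd(np.full(50, 0.9))
        assert sd1 == 0.0 and sd2 == 0.0

    def test_variance_identity(self, rng):
        x = 0.9 + 0.05 * rng.standard_normal(200)
        sd1, sd2 = poincare_sd(x)
        a, b = x[:-1], x[1:]
        assert sd1**2 + sd2**2 == pytest.approx(
            np.var(a, ddof=1) + np.var(b, ddof=1), abs=1e-12
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            poincare_sd(np.array([0.8, 0.9]))


class TestEntropies:
    def test_constant_series_apen_zero(self):
        assert approximate_entropy(np.full(60, 0.8)) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_apen_equals_bruteforce(self, seed):
        r_ = np.random.default_rng(seed)
        x = 0.9 + 0.04 * r_.standard_normal(80)
        tol = 0.2 * np.std(x, ddof=1)
        assert approximate_entropy(x, 2, tol) == pytest.approx(
            apen_bruteforce(list(x), 2, tol), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sampen_equals_bruteforce(self, seed):
        r_ = np.random.default_rng(seed)
        x = 0.9 + 0.04 * r_.standard_normal(80)
        tol = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x, 2, tol) == pytest.approx(
            sampen_bruteforce(list(x), 2, tol), abs=1e-12
        )

    def test_period_two_series_sampen_zero(self):
        x = np.tile([0.8, 1.0], 40)
        assert sample_entropy(x, 2, r=0.05) == 0.0

    def test_noise_more_irregular_than_periodic(self):
        wins = 0
        for s in range(100):
            r_ = np.random.default_rng(s)
            noise = 0.9 + 0.1 * r_.standard_normal(120)
            periodic = 0.9 + 0.1 * np.tile([1.0, -1.0], 60)
            tol = 0.2 * np.std(noise, ddof=1)
            wins += approximate_entropy(noise, 2, tol) > approximate_entropy(
                periodic, 2, tol
            )
        assert wins >= 95

    def test_sampen_non_increasing_in_r(self, rng):
        x = 0.9 + 0.05 * rng.standard_normal(150)
        rs = np.linspace(0.01, 0.1, 6)
        vals = [sample_entropy(x, 2, r) for r in rs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_sampen_nonnegative_when_defined(self, rng):
        for _ in range(10):
            x = 0.9 + 0.03 * rng.standard_normal(100)
            v = sample_entropy(x)
            assert np.isnan(v) or v >= 0


class TestCorrelationDimension:
    def test_line_has_dimension_one(self, rng):
        pts = rng.uniform(0, 1, 400)[:, None] * np.ones((1, 3))
        assert 0.8 <= correlation_dimension_points(pts) <= 1.2

    def test_plane_has_dimension_two(self, rng):
        pts = np.c_[rng.uniform(0, 1, (600, 2)), np.zeros(600)]
        assert 1.7 <= correlation_dimension_points(pts) <= 2.3

    def test_correlation_sum_non_decreasing(self, rng):
        pts = rng.standard_normal((200, 3))
        d = np.sqrt(np.sum((pts[:, None] - pts[None]) ** 2, axis=2))
        iu = np.triu_indices(200, k=2)
        dist = np.sort(d[iu])
        radii = np.logspace(np.log10(dist[5]), np.log10(dist[-1]), 20)
        c = np.searchsorted(dist, radii, side="right")
        assert np.all(np.diff(c) >= 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlation_dimension(np.full(50, 0.9))


class TestDFA:
    def test_white_noise_exponent_half(self):
        a1s = [dfa(np.random.default_rng(s).standard_normal(1000))[0]
               for s in range(50)]
        assert np.mean(a1s) == pytest.approx(0.5, abs=0.1)

    def test_integrated_noise_exponent_three_halves(self):
        a1s = [
            dfa(np.cumsum(np.random.default_rng(s).standard_normal(1000)))[0]
            for s in range(50)
        ]
        assert np.mean(a1s) == pytest.approx(1.5, abs=0.15)

    def test_fluctuations_positive_and_non_decreasing(self, rng):
        x = rng.standard_normal(1000)
        ns, fs = dfa_profile(x, 4, 64)
        assert np.all(fs > 0)
        assert np.all(np.diff(fs) >= 0)

    def test_short_series_alpha2_missing(self):
        x = np.random.default_rng(0).standard_normal(100)
        a1, a2 = dfa(x)
        assert np.isfinite(a1) and np.isnan(a2)


class TestRQA:
    CFG = EmbeddingConfig(m=3, tau=1, theiler=1, l_min=2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_bruteforce_matrix_scan(self, seed):
        r_ = np.random.default_rng(seed)
        x = 0.9 + 0.04 * r_.standard_normal(55)
        tol = np.sqrt(3) * np.std(x, ddof=1)
        got = recurrence_quantification(x, self.CFG, r=tol)
        want = rqa_bruteforce(list(x), 3, 1, tol, 1, 2)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_periodic_series_fully_deterministic(self):
        x = np.tile([0.7, 0.9, 1.1], 20)
        cfg = EmbeddingConfig(m=2, tau=1, theiler=1, l_min=2)
        out = recurrence_quantification(x, cfg, r=0.05)
        assert out["DET"] == pytest.approx(100.0)
        # longest diagonal = longest offset-3 line = n_embedded − 3
        assert out["L_max"] == x.size - 1 - 3

    def test_single_line_length_zero_entropy(self):
        # well-separated base values with one repeated block: exactly one
        # diagonal line, so the line-length distribution is degenerate
        base = 0.5 + 0.06 * np.arange(16)
        x = np.concatenate([base, base[:5]])
        cfg = EmbeddingConfig(m=2, tau=1, theiler=1, l_min=2)
        out = recurrence_quantification(x, cfg, r=0.01)
        assert out["L_max"] == out["L_mean"]
        assert out["ShanEn"] == 0.0

    def test_no_recurrences_reported_missing(self):
        x = np.arange(1.0, 2.0, 0.02)  # strictly increasing, tiny radius
        cfg = EmbeddingConfig(m=2, tau=1, theiler=1, l_min=2)
        out = recurrence_quantification(x, cfg, r=1e-6)
        assert out["REC"] == 0.0
        assert np.isnan(out["DET"])


class TestShiftInvariance:
    def test_all_measures_invariant_to_constant_offset(self, rng):
        x = 0.9 + 0.05 * rng.standard_normal(200)
        y = x + 0.35
        assert approximate_entropy(x) == pytest.approx(approximate_entropy(y), abs=1e-12)
        sx, sy = sample_entropy(x), sample_entropy(y)
        assert sx == pytest.approx(sy, abs=1e-12)
        np.testing.assert_allclose(poincare_sd(x), poincare_sd(y), atol=1e-12)
        assert dfa(x)[0] == pytest.approx(dfa(y)[0], abs=1e-10)
        assert correlation_dimension(x) == pytest.approx(
            correlation_dimension(y), abs=1e-8
        )
        a = recurrence_quantification(x)
        b = recurrence_quantification(y)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-10), key
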