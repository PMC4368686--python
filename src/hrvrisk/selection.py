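"""Feature selection: chi-squared ranking, correlation-based subset
selection (CFS) and random-forest importance.

All three operate on the training partition only; the pipeline enforces
this by handing them nothing else. Continuous features are discretized
by equal-frequency binning (10 bins by default) for both the chi-squared
statistic and the symmetrical-uncertainty correlations used by CFS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split


@dataclass
class SelectionResult:
    """Ranking and selected subset from one selection method."""

    method: str
    ranking: list[tuple[str, float]]
    selected_subset: list[str]
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ranking": [{"feature": f, "score": s} for f, s in self.ranking],
            "selected_subset": self.selected_subset,
            "parameters": self.parameters,
        }


def _feature_columns(table: pd.DataFrame, label: str) -> list[str]:
    drop = {label, "group", "segment_start", "nonstationarity_index",
            "non_stationary_fallback"}
    return [c for c in table.columns
            if c not in drop and pd.api.types.is_numeric_dtype(table[c])]


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; degenerate/duplicate bins merged."""
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    codes = np.zeros(x.size, dtype=int)
    xs = x[finite]
    if np.unique(xs).size <= n_bins:
        _, codes_f = np.unique(xs, return_inverse=True)
    else:
        qs = np.quantile(xs, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)
        codes_f = np.searchsorted(edges, xs, side="right")
    codes[finite] = codes_f
    codes[~finite] = codes_f.max() + 1 if xs.size else 0
    return codes


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    return np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb).astype(float)


def _chi2_statistic(codes: np.ndarray, y: np.ndarray) -> float:
    obs = _contingency(codes, y)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (obs - exp) ** 2 / exp
    return float(np.nansum(terms))


def chi2_rank(
    table: pd.DataFrame,
    label: str = "label",
    n_bins: int = 10,
    top_k: int = 10,
) -> SelectionResult:
    """Rank features by the Pearson chi-squared statistic of their
    equal-frequency discretization against the class label."""
    y = table[label].to_numpy()
    _require_both_classes(y)
    scores = []
    for col in _feature_columns(table, label):
        codes = _discretize(table[col].to_numpy(), n_bins)
        scores.append((col, _chi2_statistic(codes, y)))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return SelectionResult(
        method="chi2",
        ranking=scores,
        selected_subset=[f for f, _ in scores[:top_k]],
        parameters={"n_bins": n_bins, "top_k": top_k},
    )


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    joint = _contingency(a, b)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p * np.log(p / (pa @ pb))
    return float(np.nansum(terms))


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU(A, B) = 2·I(A;B)/(H(A)+H(B)) on discrete codes, in [0, 1]."""
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0:
        return 0.0
    return 2.0 * _mutual_information(a, b) / (ha + hb)


def cfs_merit(
    su_class: np.ndarray, su_pairs: np.ndarray, subset: list[int]
) -> float:
    """CFS merit k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) of a feature subset."""
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean(su_class[subset]))
    if k == 1:
        return r_cf
    idx = np.asarray(subset)
    block = su_pairs[np.ix_(idx, idx)]
    r_ff = float(np.sum(np.triu(block, 1)) / (k * (k - 1) / 2))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def cfs_select(
    table: pd.DataFrame,
    label: str = "label",
    n_bins: int = 10,
    stale_limit: int = 5,
) -> SelectionResult:
    """Correlation-based feature selection with best-first forward search.

    Subset merit rewards features correlated with the class (mean
    symmetrical uncertainty r̄_cf) and penalizes inter-feature
    redundancy (r̄_ff); the search stops after ``stale_limit``
    non-improving expansions and returns the best subset seen.
    """
    y = table[label].to_numpy()
    _require_both_classes(y)
    cols = _feature_columns(table, label)
    codes = [_discretize(table[c].to_numpy(), n_bins) for c in cols]
    su_class = np.array([symmetrical_uncertainty(c, y) for c in codes])
    p = len(cols)
    su_pairs = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            su_pairs[i, j] = su_pairs[j, i] = symmetrical_uncertainty(codes[i], codes[j])
    if not np.any(su_class > 0):
        return SelectionResult(
            method="cfs", ranking=sorted(zip(cols, su_class), key=lambda t: -t[1]),
            selected_subset=[], parameters={"n_bins": n_bins, "warning": "no feature "
                                            "positively associated with the class"},
        )
    # best-first forward search over subsets
    best_subset: list[int] = []
    best_merit = 0.0
    frontier: list[tuple[float, list[int]]] = [(0.0, [])]
    visited: set[frozenset] = {frozenset()}
    stale = 0
    while frontier and stale < stale_limit:
        frontier.sort(key=lambda t: -t[0])
        _, current = frontier.pop(0)
        improved = False
        for cand in range(p):
            if cand in current:
                continue
            subset = current + [cand]
            key = frozenset(subset)
            if key in visited:
                continue
            visited.add(key)
            merit = cfs_merit(su_class, su_pairs, subset)
            frontier.append((merit, subset))
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, subset
                improved = True
        stale = 0 if improved else stale + 1
    ranking = sorted(zip(cols, su_class), key=lambda t: (-t[1], t[0]))
    return SelectionResult(
        method="cfs",
        ranking=ranking,
        selected_subset=[cols[i] for i in sorted(best_subset)],
        parameters={"n_bins": n_bins, "stale_limit": stale_limit,
                    "merit": best_merit},
    )


def rf_importance(
    table: pd.DataFrame,
    label: str = "label",
    n_trees: int = 300,
    seed: int = 0,
    n_repeats: int = 10,
) -> SelectionResult:
    """Permutation importance from a random forest.

    The forest is fitted on an internal stratified 70% split and the
    mean decrease in held-out accuracy under feature permutation is
    measured on the remaining 30%; deterministic under ``seed``.
    """
    y = table[label].to_numpy()
    _require_both_classes(y)
    cols = _feature_columns(table, label)
    X = table[cols].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=0.7, stratify=y, random_state=seed
    )
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(X_tr, y_tr)
    imp = permutation_importance(
        rf, X_te, y_te, n_repeats=n_repeats, random_state=seed, scoring="accuracy"
    )
    ranking = sorted(
        zip(cols, imp.importances_mean.tolist()), key=lambda t: (-t[1], t[0])
    )
    return SelectionResult(
        method="rf_importance",
        ranking=ranking,
        selected_subset=[f for f, s in ranking if s > 0],
        parameters={"n_trees": n_trees, "seed": seed, "n_repeats": n_repeats},
    )


def _require_both_classes(y: np.ndarray) -> None:
    vals, counts = np.unique(y, return_counts=True)
    if vals.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
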