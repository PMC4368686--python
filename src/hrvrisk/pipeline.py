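"""End-to-end orchestration: synthetic cohort (or supplied RR series)
→ artifact filtering → stationary daytime segment → 33 HRV features →
60/40 hold-out → feature selection and 10-fold-CV model tuning on the
training partition only → test-set evaluation, rule-tree classification
and a baseline-statistics table.

Every random draw derives from one master seed, so two runs with the
same configuration produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import models, selection
from .features import FEATURE_NAMES, feature_table
from .models import DEFAULT_GRIDS, EvalReport, ModelSpec, RuleTree
from .preprocess import filter_artifacts, select_stationary_segment
from .series import RRSeries
from .synthetic import CohortConfig, simulate_clinical_covariates, simulate_cohort


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    families: Sequence[str] = models.FAMILIES
    grids: dict[str, list[dict]] | None = None
    segment_duration: float = 300.0
    n_surrogates: int = 39
    cv_folds: int = 10
    chi2_top_k: int = 10
    train_frac: float = 0.6
    with_covariates: bool = True
    rule_tree: RuleTree = field(default_factory=RuleTree)

    @property
    def seed(self) -> int:
        return self.cohort.seed


def extract_cohort_features(
    series: list[RRSeries],
    labels: Sequence[int],
    config: PipelineConfig,
    seed_offset: int = 1,
) -> pd.DataFrame:
    """Filter, segment and featurize every recording of a cohort."""
    segments = []
    master = np.random.SeedSequence([config.seed, seed_offset])
    children = master.spawn(len(series))
    for rr, child in zip(series, children):
        clean = filter_artifacts(rr)
        seg = select_stationary_segment(
            clean,
            duration=config.segment_duration,
            seed=np.random.default_rng(child),
            n_surrogates=config.n_surrogates,
        )
        segments.append(seg)
    return feature_table(segments, labels=list(labels))


def select_feature_sets(
    train: pd.DataFrame, top_k: int = 10, label: str = "label"
) -> tuple[dict[str, list[str]], dict[str, selection.SelectionResult]]:
    """Run chi-squared and CFS selection on the training partition and
    return the three candidate feature sets (all 33, chi2 top-k, CFS)."""
    hrv_cols = [c for c in FEATURE_NAMES if c in train.columns]
    if not hrv_cols:  # generic feature table (e.g. simulated Gaussians)
        hrv_cols = selection._feature_columns(train, label)
    sub = train[hrv_cols + [label]]
    chi2_res = selection.chi2_rank(sub, label=label, top_k=top_k)
    cfs_res = selection.cfs_select(sub, label=label)
    sets = {"all33": hrv_cols, "chi2_10": chi2_res.selected_subset}
    if cfs_res.selected_subset:
        sets["cfs"] = cfs_res.selected_subset
    return sets, {"chi2": chi2_res, "cfs": cfs_res}


def tune_and_fit(
    train: pd.DataFrame,
    feature_sets: dict[str, list[str]],
    config: PipelineConfig,
    label: str = "label",
) -> dict[str, tuple[ModelSpec, object]]:
    """Tune every requested family on the training partition and refit
    the winner on the full training set."""
    fitted: dict[str, tuple[ModelSpec, object]] = {}
    for family in config.families:
        grid = (config.grids or DEFAULT_GRIDS).get(family, DEFAULT_GRIDS[family])
        spec = models.tune_model(
            family,
            train,
            grid=grid,
            feature_sets=feature_sets,
            k=config.cv_folds,
            seed=config.seed,
            label=label,
        )
        fitted[family] = (spec, models.fit_model(spec, train, label=label))
    return fitted


def run_full_pipeline(
    config: PipelineConfig | None = None,
    series: list[RRSeries] | None = None,
    cohort_table: pd.DataFrame | None = None,
) -> dict:
    """Run the whole analysis and return a JSON-serializable report.

    When ``series`` is not given, a synthetic cohort is simulated from
    ``config.cohort``. The report contains per-family test evaluations,
    the selection reports, rule-tree performance on the test partition
    and on the full cohort, single-parameter echographic comparators and
    the baseline table.
    """
    config = config or PipelineConfig()
    if series is None:
        series, cohort_table = simulate_cohort(config.cohort)
    assert cohort_table is not None
    feats = extract_cohort_features(series, cohort_table["label"], config)
    if config.with_covariates:
        feats = simulate_clinical_covariates(feats, seed=config.seed + 7)

    train, test = models.holdout_split(
        feats, train_frac=config.train_frac, stratified=True, seed=config.seed
    )
    feature_sets, selection_reports = select_feature_sets(train, config.chi2_top_k)
    fitted = tune_and_fit(train, feature_sets, config)

    evaluations: dict[str, EvalReport] = {}
    for family, (spec, est) in fitted.items():
        evaluations[family] = models.evaluate(est, spec, test)
    best_family = max(evaluations, key=lambda f: evaluations[f].auc)

    rule_test = models.rule_tree_evaluate(test, config.rule_tree)
    rule_all = models.rule_tree_evaluate(feats, config.rule_tree)

    report: dict = {
        "seed": config.seed,
        "n_subjects": int(len(feats)),
        "n_high_risk": int(feats["label"].sum()),
        "split": {"n_train": int(len(train)), "n_test": int(len(test)),
                  "n_test_high_risk": int(test["label"].sum())},
        "selection": {k: v.to_dict() for k, v in selection_reports.items()},
        "models": {f: r.to_dict() for f, r in evaluations.items()},
        "best_family": best_family,
        "rule_tree": {
            "thresholds": vars(config.rule_tree),
            "test": rule_test.to_dict(),
            "cohort": rule_all.to_dict(),
        },
    }
    if config.with_covariates:
        for param in ("lvmi", "imt"):
            rep = models.threshold_classifier_roc(
                test[param].to_numpy(), test["label"].to_numpy()
            )
            report.setdefault("echographic", {})[param] = rep.to_dict()
        report["baseline_table"] = (
            models.baseline_table(
                feats.drop(
                    columns=list(FEATURE_NAMES)
                    + ["segment_start", "nonstationarity_index",
                       "non_stationary_fallback"],
                    errors="ignore",
                )
            )
            .reset_index()
            .to_dict(orient="records")
        )
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys) so identical runs are
    byte-identical."""
    return json.dumps(report, sort_keys=True, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
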