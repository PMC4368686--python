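"""Assembly of the full 33-measure HRV feature battery for a segment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import linear, nonlinear
from .series import RRSegment

#: Canonical order of the 33 HRV measures (time domain, frequency
#: domain, then nonlinear), used for every feature table and CSV.
FEATURE_NAMES: tuple[str, ...] = (
    "AVNN", "SDNN", "RMSSD", "NN50", "pNN50", "HRVTi", "TINN",
    "VLF", "LF", "HF", "TP",
    "VLF_pct", "LF_pct", "HF_pct", "LF_nu", "HF_nu", "LF_HF",
    "VLF_peak", "LF_peak", "HF_peak",
    "SD1", "SD2",
    "AppEn", "SampEn", "CD", "Alpha1", "Alpha2",
    "REC", "DET", "L_mean", "L_max", "ShanEn", "DIV",
)


def hrv_features(
    segment: RRSegment,
    embedding: nonlinear.EmbeddingConfig | None = None,
) -> dict[str, float]:
    """Compute all 33 HRV measures for one stationary 5-minute segment."""
    x = segment.intervals
    out: dict[str, float] = {}
    out.update(linear.time_domain_features(segment))
    spectrum = linear.lomb_psd(segment)
    out.update(linear.frequency_domain_features(spectrum))
    sd1, sd2 = nonlinear.poincare_sd(x)
    out["SD1"], out["SD2"] = sd1, sd2
    out["AppEn"] = nonlinear.approximate_entropy(x)
    out["SampEn"] = nonlinear.sample_entropy(x)
    cfg = embedding or nonlinear.EmbeddingConfig(m=10, tau=1)
    out["CD"] = nonlinear.correlation_dimension(x, cfg)
    out["Alpha1"], out["Alpha2"] = nonlinear.dfa(x)
    out.update(nonlinear.recurrence_quantification(x, cfg))
    assert set(out) == set(FEATURE_NAMES), "feature battery drifted from 33 names"
    return {k: out[k] for k in FEATURE_NAMES}


def feature_table(
    segments: list[RRSegment],
    labels: list[int] | np.ndarray | None = None,
    embedding: nonlinear.EmbeddingConfig | None = None,
) -> pd.DataFrame:
    """Feature rows for many segments; index = record id, 33 columns
    (+ segment metadata and an optional binary ``label`` column)."""
    rows = []
    for seg in segments:
        row = {"subject_id": seg.record_id, "segment_start": seg.start_time}
        row.update(hrv_features(seg, embedding))
        if seg.stationarity is not None:
            row["nonstationarity_index"] = seg.stationarity.index_of_nonstationarity
            row["non_stationary_fallback"] = seg.non_stationary_fallback
        rows.append(row)
    df = pd.DataFrame(rows).set_index("subject_id")
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    return df
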