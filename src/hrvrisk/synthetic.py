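"""Synthetic cohort generation.

Emulates the study conditions the analysis assumes: a cohort of 139
hypertensive subjects (122 event-free low-risk, 17 high-risk with a
recorded vascular event — 11 myocardial infarctions, 3 strokes, 3
syncopal events), each contributing an RR-interval recording from which
a 5-minute daytime segment is analysed.

Each subject's RR series is a mean interval plus LF and HF sinusoidal
modulations, a 1/f-weighted sum of slow sinusoids (0.003–0.04 Hz, which
gives DFA a nontrivial scaling exponent without long-memory machinery),
Gaussian beat-to-beat noise, and occasional ectopic beats (a shortened
beat with compensatory lengthening of the next). The two group profiles
are chosen so that, at ``effect_scale = 1``, high-risk subjects show
depressed HRV triangular index, depressed sample entropy, reduced LF%
and reduced correlation dimension — the geometry of the published
decision rule — while low-risk subjects sit on the other side of each
threshold. ``effect_scale`` interpolates the high-risk profile toward
the low-risk one; at 0 the groups are exchangeable.

Clinical covariates are drawn from group-specific Gaussians/Bernoullis
parameterized by the published baseline table; those printed summaries
are generative parameters here, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .series import ECTOPIC, NORMAL, RRSeries

N_ONE_OVER_F = 8  # sinusoids approximating the 1/f band
ONE_OVER_F_BAND = (0.003, 0.04)

EVENT_COUNTS = {"myocardial_infarction": 11, "stroke": 3, "syncope": 3}

#: Baseline-table generative parameters: continuous variables as
#: (mean, sd) per group, categorical as (count, group size).
TABLE1_CONTINUOUS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"low": (71.4, 7.0), "high": (74.1, 6.5)},
    "dbp": {"low": (76.3, 9.1), "high": (73.5, 8.4)},
    "sbp": {"low": (136.6, 19.5), "high": (141.7, 23.5)},
    "total_cholesterol": {"low": (175.7, 35.1), "high": (182.9, 42.7)},
    "ldl": {"low": (101.0, 30.1), "high": (102.0, 34.3)},
    "hdl": {"low": (52.4, 13.1), "high": (53.3, 15.3)},
    "bmi": {"low": (27.6, 3.9), "high": (27.9, 4.9)},
    "bsa": {"low": (1.9, 0.2), "high": (1.9, 0.2)},
    "imt": {"low": (2.3, 0.7), "high": (2.4, 1.1)},
    "lvmi": {"low": (130.1, 26.1), "high": (140.2, 25.1)},
    "ef": {"low": (59.3, 10.9), "high": (57.8, 13.0)},
}
TABLE1_CATEGORICAL: dict[str, dict[str, tuple[int, int]]] = {
    "sex_female": {"low": (41, 122), "high": (8, 17)},
    "family_history_hypertension": {"low": (41, 122), "high": (7, 17)},
    "family_history_stroke": {"low": (10, 122), "high": (3, 17)},
    "smoking": {"low": (35, 122), "high": (5, 17)},
    "diabetes": {"low": (18, 122), "high": (3, 17)},
    "alpha_blockers": {"low": (17, 122), "high": (3, 17)},
    "beta_blockers": {"low": (50, 122), "high": (6, 17)},
    "ace_inhibitor": {"low": (37, 122), "high": (8, 17)},
    "dihydropyridine": {"low": (27, 122), "high": (7, 17)},
}


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one subject's RR series."""

    group: str
    avnn: float
    lf_amp: float
    hf_amp: float
    lf_freq: float = 0.10
    hf_freq: float = 0.25
    one_over_f_amp: float = 0.02
    noise_sd: float = 0.02
    ectopy_prob: float = 0.0
    sdnn_target: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("low_risk", "high_risk"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.3 <= self.avnn <= 2.0:
            raise ValueError("avnn must lie in [0.3, 2.0] s")
        for name in ("lf_amp", "hf_amp", "one_over_f_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15] Hz")
        if not 0.15 <= self.hf_freq <= 0.4:
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.4] Hz")
        if not 0.0 <= self.ectopy_prob <= 0.1:
            raise ValueError("ectopy_prob must lie in [0, 0.1]")

    @property
    def expected_sdnn(self) -> float:
        """SDNN implied by the component amplitudes (uncorrelated sum)."""
        if self.sdnn_target is not None:
            return self.sdnn_target
        return float(
            np.sqrt(
                self.lf_amp**2 / 2
                + self.hf_amp**2 / 2
                + self.one_over_f_amp**2
                + self.noise_sd**2
            )
        )


#: Default group profiles; calibrated so expected HRVTi, SampEn, LF% and
#: CD straddle the decision-rule thresholds at effect_scale = 1.
LOW_RISK_PROFILE = SubjectProfile(
    group="low_risk",
    avnn=0.80,
    lf_amp=0.040,
    hf_amp=0.020,
    one_over_f_amp=0.020,
    noise_sd=0.050,
    ectopy_prob=0.005,
)
HIGH_RISK_PROFILE = SubjectProfile(
    group="high_risk",
    avnn=0.85,
    lf_amp=0.008,
    hf_amp=0.004,
    one_over_f_amp=0.028,
    noise_sd=0.0025,
    ectopy_prob=0.005,
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort run."""

    n_low: int = 122
    n_high: int = 17
    profile_low: SubjectProfile = LOW_RISK_PROFILE
    profile_high: SubjectProfile = HIGH_RISK_PROFILE
    effect_scale: float = 1.0
    duration_s: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("both groups need at least one subject")

    def effective_high_profile(self) -> SubjectProfile:
        """High-risk profile interpolated toward low-risk by effect_scale."""
        s = self.effect_scale
        lo, hi = self.profile_low, self.profile_high

        def mix(a: float, b: float) -> float:
            return a + s * (b - a)

        return replace(
            lo,
            group="high_risk",
            avnn=mix(lo.avnn, hi.avnn),
            lf_amp=mix(lo.lf_amp, hi.lf_amp),
            hf_amp=mix(lo.hf_amp, hi.hf_amp),
            lf_freq=mix(lo.lf_freq, hi.lf_freq),
            hf_freq=mix(lo.hf_freq, hi.hf_freq),
            one_over_f_amp=mix(lo.one_over_f_amp, hi.one_over_f_amp),
            noise_sd=mix(lo.noise_sd, hi.noise_sd),
            ectopy_prob=mix(lo.ectopy_prob, hi.ectopy_prob),
            sdnn_target=None,
        )


def _one_over_f_components(
    amp: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequencies, amplitudes and phases of the 1/f surrogate band.

    Amplitudes follow power ∝ 1/f (amplitude ∝ f^{-1/2}) over the band,
    scaled so the summed RMS equals ``amp``.
    """
    freqs = np.geomspace(*ONE_OVER_F_BAND, N_ONE_OVER_F)
    a = freqs**-0.5
    a *= amp / np.sqrt(np.sum(a**2) / 2.0)
    phases = rng.uniform(0, 2 * np.pi, N_ONE_OVER_F)
    return freqs, a, phases


def simulate_rr_series(
    profile: SubjectProfile,
    duration_s: float,
    seed: int | np.random.SeedSequence,
    record_id: str = "synthetic",
) -> RRSeries:
    """Generate one RR-interval series from a subject profile.

    Beat ``i`` occurs at ``t_i = t_{i-1} + IBI_i`` with the inter-beat
    interval the sum of the mean interval, LF/HF sinusoids evaluated at
    the previous beat time, the 1/f component and Gaussian noise. With
    probability ``ectopy_prob`` a beat is shortened to 0.6·IBI with
    compensatory lengthening of the next and labelled ectopic.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60 s")
    rng = np.random.default_rng(seed)
    f1, a1, p1 = _one_over_f_components(profile.one_over_f_amp, rng)
    det_amp = profile.lf_amp + profile.hf_amp + float(np.sum(a1))
    if profile.avnn - det_amp - 5 * profile.noise_sd <= 0:
        raise ValueError(
            "non-physiological profile: modulation amplitudes "
            f"({det_amp:.3f} s deterministic + {profile.noise_sd:.3f} s noise) "
            f"can drive intervals at mean {profile.avnn:.3f} s negative"
        )
    phi = rng.uniform(0, 2 * np.pi)
    psi = rng.uniform(0, 2 * np.pi)
    intervals: list[float] = []
    t = 0.0
    while True:
        ibi = (
            profile.avnn
            + profile.lf_amp * np.sin(2 * np.pi * profile.lf_freq * t + phi)
            + profile.hf_amp * np.sin(2 * np.pi * profile.hf_freq * t + psi)
            + float(np.sum(a1 * np.sin(2 * np.pi * f1 * t + p1)))
        )
        if profile.noise_sd > 0:
            ibi += rng.normal(0.0, profile.noise_sd)
        if ibi <= 0:
            raise ValueError("non-physiological profile produced a negative interval")
        if t + ibi > duration_s + 1e-9:
            break
        intervals.append(ibi)
        t += ibi
    x = np.asarray(intervals)
    labels = np.full(x.size, NORMAL, dtype=object)
    if profile.ectopy_prob > 0 and x.size > 2:
        ect = rng.random(x.size - 1) < profile.ectopy_prob
        touched = np.zeros(x.size, dtype=bool)
        for i in np.flatnonzero(ect):
            if touched[i] or touched[i + 1]:
                continue
            shift = 0.4 * x[i]
            x[i] -= shift
            x[i + 1] += shift
            labels[i] = ECTOPIC
            touched[i] = touched[i + 1] = True
    return RRSeries(intervals=x, beat_labels=labels, record_id=record_id)


def simulate_cohort(config: CohortConfig) -> tuple[list[RRSeries], pd.DataFrame]:
    """Generate the labelled RR series of a full cohort.

    Returns the series plus a cohort table with ``subject_id``, ``group``
    and binary ``label`` (1 = high risk). Per-subject seeds are spawned
    deterministically from ``config.seed``.
    """
    high_profile = config.effective_high_profile()
    series: list[RRSeries] = []
    rows = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_low + config.n_high)
    for idx in range(config.n_low + config.n_high):
        is_high = idx >= config.n_low
        profile = high_profile if is_high else config.profile_low
        sid = f"subj{idx:03d}"
        series.append(
            simulate_rr_series(profile, config.duration_s, children[idx], record_id=sid)
        )
        rows.append({"subject_id": sid, "group": profile.group, "label": int(is_high)})
    table = pd.DataFrame(rows).set_index("subject_id")
    return series, table


def simulate_feature_table(
    n_low: int,
    n_high: int,
    n_informative: int,
    n_noise: int,
    effect_size: float = 1.0,
    correlation: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast Gaussian feature table with a planted group separation.

    Informative features share a within-block correlation and receive a
    standardized mean shift of ``effect_size`` in the high-risk group;
    noise features are independent standard Gaussians. Used as the quick
    test surface for the selection and classification stages.
    """
    if n_informative + n_noise < 1:
        raise ValueError("need at least one feature")
    if not abs(correlation) < 1:
        raise ValueError("within-block correlation must satisfy |rho| < 1")
    k = n_informative
    if k > 1 and correlation < -1.0 / (k - 1):
        raise ValueError("correlation makes the block covariance degenerate")
    rng = np.random.default_rng(seed)
    n = n_low + n_high
    cols = [f"f{i:02d}" for i in range(k + n_noise)]
    X = np.empty((n, k + n_noise))
    if k:
        cov = np.full((k, k), correlation, dtype=float)
        np.fill_diagonal(cov, 1.0)
        X[:, :k] = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        X[n_low:, :k] += effect_size
    if n_noise:
        X[:, k:] = rng.standard_normal((n, n_noise))
    df = pd.DataFrame(X, columns=cols)
    df.index = [f"subj{i:03d}" for i in range(n)]
    df.index.name = "subject_id"
    df["label"] = np.r_[np.zeros(n_low, dtype=int), np.ones(n_high, dtype=int)]
    return df


def simulate_clinical_covariates(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Append baseline clinical covariates drawn per group.

    Continuous covariates come from group-specific Gaussians and binary
    covariates from group-specific Bernoullis, both parameterized by the
    published baseline characteristics; requires a binary ``label``
    column (1 = high risk).
    """
    if "label" not in cohort.columns:
        raise ValueError("cohort table must carry a binary 'label' column")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    grp = np.where(out["label"].to_numpy() == 1, "high", "low")
    n = len(out)
    for name, params in TABLE1_CONTINUOUS.items():
        vals = np.empty(n)
        for g in ("low", "high"):
            mask = grp == g
            mean, sd = params[g]
            vals[mask] = rng.normal(mean, sd, mask.sum())
        out[name] = vals
    for name, params in TABLE1_CATEGORICAL.items():
        vals = np.empty(n, dtype=int)
        for g in ("low", "high"):
            mask = grp == g
            count, total = params[g]
            vals[mask] = rng.random(mask.sum()) < count / total
        out[name] = vals
    return out


def devereux_lvmi(ivs_cm: float, lvidd_cm: float, pw_cm: float, bsa_m2: float) -> float:
    """Left ventricular mass index (g/m²), ASE-cube Devereux formula.

    LV mass (g) = 0.8·1.04·[(IVS+LVIDd+PW)³ − LVIDd³] + 0.6, with wall
    thicknesses and diastolic diameter in cm, indexed to body surface
    area. Wall measurements may be zero (degenerate cavity-only case)
    but the cavity diameter and body surface area must be positive.
    """
    if lvidd_cm <= 0 or bsa_m2 <= 0:
        raise ValueError("lvidd_cm and bsa_m2 must be positive")
    if ivs_cm < 0 or pw_cm < 0:
        raise ValueError("wall thicknesses must be non-negative")
    mass = 0.8 * 1.04 * ((ivs_cm + lvidd_cm + pw_cm) ** 3 - lvidd_cm**3) + 0.6
    return mass / bsa_m2
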