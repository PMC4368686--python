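# Methods

This note records the models, conventions and numerical choices behind
`hrvrisk`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## RR model and the synthetic cohort

The generator works directly at the RR level — no ECG waveform or QRS
detection is emulated, since the analysis consumes beat intervals. Beat
`i` occurs at `t_i = t_{i-1} + IBI_i` with

    IBI_i = AVNN + a_LF sin(2π f_LF t + φ) + a_HF sin(2π f_HF t + ψ)
            + Σ_k a_k sin(2π f_k t + θ_k) + ε_i,   ε_i ~ N(0, σ²)

The third term is the slow-wave band: 8 sinusoids log-spaced over
0.003–0.04 Hz with power ∝ 1/f, scaled to a target RMS. This gives the
detrended-fluctuation exponents a nontrivial value without long-memory
machinery and fills the VLF band the way slow regulatory rhythms do.
With per-beat probability `ectopy_prob` a beat is shortened to 0.6·IBI
and the next lengthened by the same amount (a compensated premature
beat); ectopy never stacks on an already-modified beat.

Default group profiles (units: seconds, Hz):

| parameter        | low risk | high risk |
|------------------|---------:|----------:|
| AVNN             | 0.80     | 0.85      |
| a_LF (0.10 Hz)   | 0.040    | 0.008     |
| a_HF (0.25 Hz)   | 0.020    | 0.004     |
| 1/f RMS          | 0.020    | 0.028     |
| noise SD         | 0.050    | 0.0025    |
| ectopy prob      | 0.005    | 0.005     |

The high-risk profile is a regular, slow-wave-dominated, low-noise
rhythm; the low-risk profile is noise-rich with a strong LF share. The
amplitudes were calibrated once, at design time, so the group
expectations of the four decision-rule variables straddle the published
cuts (HRVTi 13.6, SampEn 0.997, LF% 18.1, CD 3.43). `effect_scale`
linearly interpolates the high-risk profile toward the low-risk one;
at 0 the groups are exchangeable, which is the null used by the
acceptance suite. Per-subject randomness comes from
`SeedSequence(seed).spawn(n)`, so cohorts are bit-reproducible and
subjects independent.

Default record length is 15 minutes — long enough that a random
5-minute segment is a genuine draw, short enough for desk-scale runs;
the clinical setting (nominal 24 h Holter) differs only in the size of
the candidate pool. Clinical covariates are drawn from group-specific
Gaussians/Bernoullis parameterized by the published baseline table;
those printed summaries are generative constants, not fitted values.

What the generator does **not** emulate: baroreflex/respiratory
coupling, circadian structure, realistic ectopy morphology beyond the
compensatory-pause pattern, missing data, or detector jitter. Passing
tests therefore demonstrate that the *analysis machinery* recovers a
planted structure of the stated geometry — not that it would achieve
the same operating points on clinical Holter data. The planted
separation is clean, so classifier metrics on the synthetic cohort
saturate near 100%, well above the published clinical figures.

## Stationary segment selection

The stationarity screen follows the surrogate scheme of Borgnat &
Flandrin (time–frequency features against phase-randomized surrogates);
the published analysis cites the method without parameters, so the
realization here is this package's own: cubic-spline resampling to
4 Hz, Hann-windowed local spectra over 50%-overlapping windows of a
quarter of the segment, symmetric Kullback–Leibler distance between
unit-mass local and global spectra (unit mass makes the verdict
invariant to rescaling the series), index = variance of the distances,
39 surrogates and a 95th-percentile threshold (a one-sided rank test at
the exact 2.5% level; measured false-alarm rate on stationary noise is
~5% because the index is compared to an interpolated percentile rather
than the maximum). Candidate 5-minute windows are drawn uniformly
(restricted to 08:00–20:00 when the record carries a wall clock —
"daytime" is not defined in the source and this window is our choice);
after 50 failures the least non-stationary candidate is returned,
flagged. A known blind spot: a linear drift slow enough to look
identical in every analysis window leaves the local spectral *shape*
unchanged and is not rejected; level shifts and variance changes are
caught reliably (step detection ~100% in the test suite).

Artifact filtering (0.3–2.0 s absolute range; >20% deviation from the
5-beat running median, the tested beat excluded from its own median)
follows common HRV practice; the source is silent on artifact handling.
Features are computed on the post-filter intervals. "5 minutes" means
accumulating intervals until ≥300 s, not a fixed beat count.

## Feature conventions

- SDNN and every other dispersion use the n−1 estimator.
- HRVTi/TINN histogram: bin width 1/128 s, edges aligned on multiples
  of 1/128 s. TINN minimizes the squared error of a triangle with apex
  fixed at the modal bin over all (left, right) base endpoints.
- Spectrum: Lomb–Scargle on beat-time-indexed intervals (no
  resampling), frequency step 1/(4·span), renormalized so the
  trapezoidal integral over (0, 0.4] Hz equals the n−1 interval
  variance (Parseval-consistent). Powers are reported in s² throughout.
  Bands are half-open, closed on the right — a sample at exactly
  0.04 Hz belongs to VLF — and TP ≡ VLF + LF + HF. Peak frequencies are
  grid maxima (no parabolic interpolation).
- Entropies: m = 2, r = 0.2·SDNN, Chebyshev distance, natural logs.
  ApEn includes self-matches (Pincus); SampEn excludes them and uses
  N−m templates at both lengths (Richman–Moorman); undefined SampEn
  (no matches) is a missing value.
- Correlation dimension: embedding m = 10, τ = 1, Theiler window 1,
  24 logarithmic radii between the 2nd and 98th distance percentiles,
  correlation sums restricted to 0.01 ≤ C(r) ≤ 0.5, and the slope taken
  over the 5-point window of most stable local slope. The embedding
  defaults follow prevailing HRV-software convention and are exposed in
  `EmbeddingConfig`.
- DFA: first-order detrending, non-overlapping boxes, partial final box
  discarded; α₁ over boxes 4–16, α₂ over 16–64. Fluctuations are
  debiased by the exact white-noise finite-size factor
  √(1 − 4/n²) (E[F²(n)] = σ²(n²−4)/(15n) for DFA1 on white noise),
  without which α₁ of white noise is biased to ≈0.59 at these scales.
- Recurrence analysis: same embedding, Euclidean distance, radius
  √m·SDNN (embedded distances grow like √m, so this keeps the
  recurrence rate comparable across m), diagonal lines of length ≥2
  from the upper triangle, Shannon entropy of the line-length
  distribution in nats, DIV = 1/L_max.

Tying every tolerance to SDNN makes all nonlinear measures invariant to
adding a constant to the series; the suite asserts this numerically.

## Selection and classification

Chi-squared ranking and the CFS correlations both discretize features
into 10 equal-frequency bins (the selection criterion is published, the
discretizer is not; equal-frequency makes the scores invariant to
monotone feature transforms). CFS uses symmetrical uncertainty and
best-first forward search with a 5-expansion stale limit. RF importance
is permutation importance on an internal stratified 70/30 split —
"mean decrease in out-of-sample accuracy" — rather than per-tree OOB
importance, which would require private scikit-learn APIs.

The six classifier families are deliberately library-backed (they are
off-the-shelf methods in the source analysis); the Weka-era
hyperparameter names map to scikit-learn as follows: the C4.5
confidence factor CF becomes cost-complexity pruning with
α = 0.01·(0.5 − CF) (smaller CF ⇒ heavier pruning), MI is the minimum
leaf size, AdaBoost boosts that same tree, the MLP has one hidden layer
of (features+2)/2 units with SGD (LR, momentum M, NE epochs), and the
SVM is RBF with gamma G on standardized inputs. Tuning maximizes
stratified 10-fold CV accuracy over hyperparameters × feature sets
(all 33, chi² top-10, CFS subset) on the training partition only; ties
break toward fewer features, then lexicographic hyperparameters. The
60/40 hold-out floors the train count per class (83/56 at 139 subjects,
7 high-risk in the test set). Accuracy CIs use the Wilson score method.
ROC scores are class-1 probabilities, or the decision function for the
SVM.

The decision-rule classifier uses strict inequalities exactly as
printed; equality falls through to the "not less / not greater" branch.
The source contains a genuine contradiction for the LF cut (0.011 s² in
the results text, 0.001 s² in the figure caption); the default is
0.011 s² and the field is exposed on `RuleTree` rather than silently
resolved. Since the rule is a single operating point, its AUC equals
(SEN+SPE)/2.

## Baseline statistics

Two-group continuous comparisons use the pooled-variance Student t-test
computed from summary statistics (df = n₁+n₂−2); categorical rows use
Pearson chi-squared on the 2×2 table without continuity correction.
These conventions reproduce the published p-values for age (0.136),
LVMi (0.135) and sex (0.277) from the printed summaries to ±0.005. The
diastolic-pressure row (printed 0.204) is not recovered by either the
Student (0.233) or Welch (0.216) convention and is documented as such
in the suite rather than forced.

## Problem sizes and determinism

The acceptance suite runs the full pipeline once on the default cohort
(139 subjects, 15-minute records) and, for the null case, eight
effect-scale-0 cohorts with a one-combination tuning grid per family;
the null check is that each family's 95% t-interval of mean test AUC
across seeds covers 50% (a per-run CI rule would be expected to fail
~5% of the time under the null by construction). All randomness in the
pipeline descends from one master seed via `SeedSequence` spawning, and
reports serialize with sorted keys, so identical configurations produce
byte-identical JSON.

## Known limitations

- The WFDB annotation codec is minimal (interval words + SKIP escape;
  AUX/NUM/SUB/CHN skipped) — sufficient for beat-time round-trips, not
  a general WFDB implementation.
- The stationarity index is blind to pure in-window linear drift (see
  above).
- Embedding and tolerance defaults for the nonlinear battery follow
  field convention rather than a published parameter table, and CD/RQA
  values are convention-dependent; cross-study comparison requires
  matching `EmbeddingConfig`.
- The synthetic cohort's separation is idealized; published clinical
  operating points are not reproducible from it, only the qualitative
  structure (HRV battery ≫ single echographic parameter; decision-rule
  thresholds discriminating as printed).
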