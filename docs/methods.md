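# Methods

This note documents the models implemented in `conncpm`, the synthetic
cohort generator used to exercise them, the numerical choices made where a
convention had to be fixed, and the known limitations of what the test
suite demonstrates.

## 1. Connectome construction

A session fingerprint is built from five BOLD runs of 245 timepoints at
TR = 1.75 s over R = 215 ROIs (defaults; all are configurable):

1. **Nuisance regression.** Each ROI series is replaced by its OLS
   residual on an intercept plus nine regressors: six motion parameters
   and the mean white-matter, CSF and global signals. Residuals are
   orthogonal to the regressors to ~1e−8 relative; rank-deficient designs
   fall back to the least-norm solution with a warning.
2. **Linear detrending** (per-ROI OLS line).
3. **Low-pass filtering** at 0.2 Hz: 4th-order Butterworth applied
   forward-backward (`scipy.signal.sosfiltfilt`), i.e. zero phase and
   8th-order magnitude. With TR = 1.75 s the Nyquist frequency is
   ≈ 0.286 Hz; the response is within 5% of unity below half the cutoff
   and ≥ 20 dB down at 1.5× the cutoff (asserted on sinusoids).
4. **Within-run z-scoring**, population-sd convention (ddof = 0). A
   constant regional series is an error naming the ROI.
5. **Concatenation** in run order (5 × 245 = 1225 timepoints), pairwise
   Pearson correlation, and Fisher r-to-z of the lower triangle with |r|
   clipped at 1 − 1e−7.

Stage order is fixed as listed: regressing confounds before detrending
prevents the trend fit from re-introducing confound structure, and
filtering after both keeps the regressors and data on the same time base.
The edge ordering convention is `numpy.tril_indices(R, −1)` — pairs (i, j)
with i > j, row-major — and is used identically by the differential power
statistic and the CPM feature indices.

## 2. Identification and differential power

The identification matrix holds Pearson correlations between every
session-B fingerprint (rows) and every session-A fingerprint (columns). A
row/column is a *hit* when its diagonal entry is the strict maximum; exact
ties count as misses (conservative and deterministic). The permutation
null shuffles the subject correspondence and records the mean of the two
directional accuracies; p-values use the add-one estimator
(1 + #{null ≥ observed}) / (n_perm + 1) and can never be zero. Confound
control regresses subject-level covariates (session order, motion-outlier
count, total brain volume) out of every edge, per session, before
identification.

Differential power: for edge e, subject i, with session values a and v,

    V_i(e) = #{j≠i : a_i v_j ≥ a_i v_i} + #{j≠i : a_j v_i ≥ a_i v_i}
    p_{e,i} = max(V_i(e), 1) / (2(N−1)),   DP(e) = Σ_i −ln p_{e,i}

Flooring the violation count at one keeps −ln finite while preserving the
rank order of edges; a completely non-discriminative edge (identical
across subjects and sessions) gets p = 1 everywhere and DP = 0. The
vectorized implementation is verified against a triple-loop enumeration to
1e−12. Suprathreshold edges are those strictly above the 99.5th
percentile of the DP distribution (linear-interpolation percentile);
node summaries count suprathreshold incident edges per ROI and take the
top ⌈0.03 R⌉ ROIs (ties broken by ascending ROI id); network summaries
report the fraction of suprathreshold edges per unordered network pair
(fractions sum to one).

## 3. Connectome-based predictive modeling

Leave-one-out over the scored subjects (subjects with missing MVIC are
excluded up front; the default cohort drops 3 of 55, leaving 52). Per
fold:

- **Covariate residualization.** MVIC ~ intercept + age + sex is fit on
  the training subjects only and its coefficients applied to the held-out
  subject. Nothing on the training side ever depends on the held-out
  score; this is asserted bit-for-bit in the tests.
- **Bootstrap feature selection.** `n_boot` iterations (protocol default
  1,000); each draws a fraction f uniformly from {0.8, 0.85, 0.9, 0.95}
  and resamples ⌊f·n_train⌋ subjects *with replacement*, then tests every
  edge's Pearson correlation with the resampled residualized scores at
  the FST (defaults scanned: 0.01, 0.005, 0.001). Inside the loop the
  test is evaluated through the exact equivalence p < FST ⇔
  |r| > r_crit(m, FST) from the t-distribution with m − 2 df; constant
  edges produced by resampling duplicates get r = NaN and never pass.
  Edges significant in ≥ 80% of iterations (inclusive, compared in
  integer counts) are retained and signed by their correlation on the
  full training fold — the stable choice when iteration signs disagree.
- **Strengths and prediction.** Retained positive and negative edges are
  averaged separately per subject (an empty set contributes 0 and is
  flagged); one OLS on d = negative − positive strength predicts the
  held-out subject. A fold with no selected edges predicts the training
  mean and is flagged rather than aborting.

Metrics: Pearson r between out-of-fold predictions and the fold-wise
residualized observed scores (with its t-test p), prediction
R² = 1 − SSE/SST — which is *not* r² and may be negative — and RMSE. The
printed study-scale pairs (e.g. r ≈ 0.42 with R² ≈ 0.10) are consistent
with this reading and not with R² = r².

**Permutation test.** Scores are shuffled across subjects while
covariates stay attached; the entire procedure (covariate removal,
selection, prediction) reruns per permutation. Permutations in which every
fold is empty record r = NaN and are excluded, with their count reported;
p uses the add-one estimator over the valid permutations.

**Random numbers.** A master seed spawns named substreams (per fold, per
permutation) via `numpy.random.SeedSequence`, so changing the number of
permutations never perturbs the fold-level bootstrap draws, and identical
configurations reproduce results bit for bit.

## 4. The synthetic cohort generator

No public data accompany the analyses, so the generator defines the study
conditions the package is tested under:

- **Edges.** `z[e,s,k] = μ_e + u[e,s] + w[e,s,k] (+ n[e,s,k])` in
  Fisher-z units, with μ = 0.30 for within-network and 0.05 for
  between-network edges, subject effect sd `sigma_subject = 0.4`, session
  effect sd `sigma_session = 0.1`, optional residual edge noise (default
  0). All effects independent across subjects, sessions and edges. The
  4:1 subject-to-session ratio puts the cohort in the
  perfect-identification regime the analyses report.
- **Parcellation.** 215 ROIs in contiguous blocks over seven networks
  (MF, FP, DM, SC, M, VIS, VA) with block sizes (29, 34, 40, 43, 27, 24,
  18); SC is deliberately the largest block.
- **Phenotype.** `mvic = β0 + β_age·age + β_sex·sex + Σ_P γ_e u[e,s] + ε`
  with age ~ Uniform(65, 87), sex 0 = female (29 of 55 female),
  β_age = −100 units/yr (weak, matching a non-significant age partial
  correlation), β_sex = 12,500 units (male − female difference of the
  order reported for dynamometer scores), ε sd 1,500. Planted edges
  (default 6) are drawn without replacement from within the SC block and
  carry strictly negative weights −|N(6000, 600²)| — the negative-network
  character of connectome predictors of strength. Exactly
  `n_missing_scores` subjects (default 3 of 55) get missing MVIC,
  stored as NaN, never 0.
- **Confound columns** (motion outliers, brain volume, session order) are
  drawn independently of the edges by default so confound-control
  analyses can be tested under the null; `confound_edge_coupling > 0`
  injects brain-volume-correlated edge structure instead.
- **Time series.** Each session's edge vector is mapped to a correlation
  matrix (inverse Fisher; eigenvalue clipping at 1e−4 with diagonal
  re-normalization, finished by a shrink-toward-identity step that
  guarantees the eigenvalue floor while keeping the unit diagonal), and
  white Gaussian vectors are colored by its Cholesky factor, then
  contaminated with a per-ROI linear trend, above-cutoff sinusoids and
  known loadings of nine simulated nuisance regressors (motion-like
  random walks, AR(1) tissue means). The preprocessing pipeline removes
  all of these by construction, which the invariance tests assert.

Because the independent-edge model is far from positive definite at
R = 215, the projection shrinks edge structure; empirically the projected
matrix's edges correlate ≈ 0.90 with the latent vector, and a fingerprint
rebuilt from 1,225 simulated timepoints correlates ≈ 0.83 — above the 0.8
recovery bound asserted in the tests, but a real attenuation worth knowing
about. Identification is unaffected (the projection is applied per
subject-session and preserves the subject-to-session signal ratio).

What the generator does **not** emulate: voxel-level imaging, head-motion
artifacts correlated with connectivity, physiological noise spectra,
spatial autocorrelation between edges sharing an ROI, and site/scanner
effects. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to real
acquisition artifacts.

## 5. Test-scale choices

Heavy checks run at reduced, stated scales chosen as the package's own
desk-scale defaults: planted-edge recovery uses 100 ROIs (4,950 edges),
52 scored subjects, FST 0.01 and 200 bootstrap iterations over three
replicate cohorts; permutation calibration uses 50 replicate null cohorts
of 20 subjects × 528 edges with 50 bootstrap iterations and 99
permutations each.

Two conditions in those checks deserve explanation:

- **Recovery is stated conditionally on realized effect size.** The
  planted-effect calibration targets a per-edge score correlation of
  |r| = 0.6 via the closed form
  r = γσ_u² / (√(σ_u²+σ_w²) · √(Pγ²σ_u² + σ_ε²)); the *realized*
  correlation in a 52-subject cohort fluctuates with sd ≈ 0.09, and a
  cohort realizing |r| ≈ 0.5 sits exactly on the 80%-retention boundary.
  The recovery tests therefore select seeded cohorts whose realized
  planted |r| lies in [0.55, 0.68] before asserting that ≥ 80% of planted
  edges appear in the consistent negative set.
- **Calibration requires an exchangeable null.** The permutation scheme
  shuffles *raw* scores while covariates stay attached to subjects, so
  its null distribution is exact only when scores are exchangeable
  across subjects. Null cohorts for the calibration check set the age
  and sex effects to zero; with a sex effect ~8× the score noise left
  in, the same scheme is measurably anticonservative at n = 20. This is
  a property of the permutation design itself and applies equally to
  real-data use: strongly covariate-driven phenotypes deserve a
  permutation scheme that shuffles residualized scores (or permutes
  within covariate strata).

## 6. Numerical conventions and degenerate inputs

- Fisher transform clips |r| at 1 − 1e−7; z-scoring uses population sd;
  percentiles use linear interpolation with strict exceedance.
- Identification ties are misses; permutation p-values use the add-one
  estimator and never report 0 (a reported p of 1/1001 means "no null
  permutation reached the observed value").
- DP floors the violation count at 1 (p_min = 1/(2(N−1))).
- Constant predictors, empty feature sets, all-empty permutations and
  singular covariate designs are flagged (or excluded with a count), not
  fatal; constant fingerprint rows, constant ROI series, non-PD targets,
  misaligned subject sets and missing confounds raise informative errors.
- Text matrices round-trip exactly at 17 significant digits; HDF5 is bit
  exact. JSON artifacts are deterministic (sorted keys, no timestamps).

## 7. Limitations

- Leave-one-out CPM prediction r is negatively biased under the null
  (training-mean predictions anticorrelate with held-out residuals);
  significance must come from the permutation test, never from the
  t-test p alone.
- The bootstrap "fraction" sample is drawn with replacement at reduced
  size; a without-replacement subsample variant is available via
  `CPMConfig(with_replacement=False)`.
- The 99.5th-percentile DP threshold and top-3% node rule are reported
  with this package's stated percentile and tie conventions; other
  reasonable conventions shift suprathreshold counts slightly.
- The additive independent-edge generator understates the spatial
  structure of real connectomes; effect sizes recovered here should not
  be read as power statements about real cohorts.
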