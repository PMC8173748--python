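# Methods

This note documents the models, numerical choices and simulation design
behind `dwiresponse`, and what the synthetic-data tests do and do not
establish about real data.

## Decay models and units

All diffusion coefficients are stored and reported in 10⁻³ mm²/s (the
conventional scale for tissue water), b-values in s/mm². The IVIM perfusion
fraction `f` is carried on the ×100 scale (9.27 means 9.27%); `f` and the
stretching exponent α are unitless.

Three forward models are implemented:

| model | form | fitted over |
|---|---|---|
| mono-exponential | S₀·exp(−b·ADC) | ALL (13 b-values), or two-point pairs (0,1000), (200,1000) |
| bi-exponential (IVIM) | S₀·[f·e^(−b·D*) + (1−f)·e^(−b·D)] | LOW: 0,10,30,50,100,150,200,500,800 |
| stretched-exponential | S₀·exp(−(b·DDC)^α) | HIGH: 0,500,800,1000,1500,2000,2500 |

The two-point ADC is the closed form ln(S₁/S₂)/(b₂−b₁). For any signal with
a perfusion compartment (f > 0), ADC₀,₁₀₀₀ > ADC₂₀₀,₁₀₀₀ because the
b = 0 sample carries the pseudodiffusion excess; equality holds iff f = 0.

## Fitting strategy

**Mono.** Unweighted linear least squares of log-signal on b. This is the
de-facto standard for ADC maps, is exactly determined on two-point subsets
(where it reproduces `adc_two_point` bit-for-bit), and needs no
initialization. A nonlinear refinement on the raw signal is available as
`method="nlls"` for users who prefer signal-domain residuals; the two differ
only in their noise weighting.

**IVIM.** Segmented initialization — log-linear D and intercept from the
b ≥ 200 points of the LOW subset, f from the intercept gap at b = 0 — then
joint bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) from five deterministic perturbations of that
start; lowest residual sum of squares wins. Deterministic (rather than
random) multi-starts keep voxel-wise maps bit-reproducible without seed
plumbing. D* is parameterized as D + gap with gap ≥ 0, so D* ≥ D holds by
construction rather than by post-hoc swapping. When the fitted f is below
0.5 (half a percent), the fast compartment is effectively absent, D* is
unidentifiable, and it is reported as NaN with
`d_star_identifiable=False`.

**Stretched.** Bounded NLLS from three deterministic starts spanning
α ∈ {0.6…1.0}, DDC from the log-linear slope of the HIGH subset.

**Bounds.** D and DDC ∈ [0.05, 4]×10⁻³ mm²/s, D* ≥ max(D, ·) with
D* ≤ ~80×10⁻³, f ∈ [0, 60] (×100), α ∈ (0.01, 1]. These bracket reported
breast-tumor values with wide margin; hitting a bound is visible in the
convergence flag and residuals, never silently clipped after the fact.

**Convergence and tolerances.** `least_squares` with ftol = xtol = gtol =
10⁻¹², max 500 function evaluations; non-convergence keeps the best
candidate and sets `converged=False`. Noiseless forward-simulated decays
round-trip to < 10⁻⁴ relative error for every model parameter (D* excepted
when f = 0, where it is undefined).

**Degenerate intensities.** Simulated Rician noise can drive magnitudes
toward (but not below) zero; measured data may contain zeros. Before any log
transform, non-positive samples are clamped to a floor (default: half the
smallest positive sample of that decay) and the clamp count is logged and
surfaced as a warning and in the run manifest.

## Synthetic data

**Noise model.** Magnitude MRI noise is Rician:
observed = sqrt((S+ε₁)² + ε₂²) with ε ~ N(0, σ²). This matters at high b,
where the decayed signal approaches the noise floor and Gaussian noise would
understate the positive bias that affects DDC/α estimation. The identity
E|noise-only| = σ·√(π/2) is used as a closed-form oracle in tests. Phantom
and fit tests use σ = S₀/50 (SNR 50 at b = 0), a realistic value for 3-T
breast DWI; the default phantom uses tumor S₀ = 600 and a fluid-like
mono-exponential background.

**Phantoms.** Ellipsoid/box regions on a grid with 2.6 × 2.6 × 3 mm voxels
(a typical breast DWI resolution); each region decays under one generating
model. Overlaps resolve by list order. Truth maps carry the generating
parameters; the implied two-point ADCs and the log-linear ADC_all of the
noiseless decay are also recorded, since those are the estimands of the
corresponding estimators.

**Cohorts.** The generator emulates a 144-patient, three-timepoint NACT
cohort: pCR prevalence 0.375 (54:90), mid-treatment imaging in 101 patients
(37 pCR : 64 non-pCR), post-treatment in 98 (33:65). For each of the nine
features (seven DWI parameters, lesion size, RER), pre-treatment values and
mid-/post-treatment changes are drawn from group-conditional normal
distributions whose means/SDs match the published group summaries the
package is calibrated to; biomarker positivity (ER, PR, HER2, Ki-67 ≥ 20%)
is group-conditional Bernoulli. In the default fixed-counts mode the group
sizes, availability and biomarker counts are exact, which reproduces the
printed cohort arithmetic (e.g. 35/54 ER-negative responders).

Approximations to be aware of:

- Features are drawn independently given response group; real ADC variants
  are strongly mutually correlated. Marginal analyses (per-feature tables,
  single-predictor ROC) are faithful; joint quantities (multivariate model
  coefficients, model AUC) are only qualitatively comparable to a real
  cohort.
- Group-conditional normality is an approximation — some real features are
  skewed (hence the rank-sum branch in the comparison machinery).
- Follow-up values are pre + Δ with Δ drawn independently of the pre value;
  no regression-to-the-mean structure.
- Dropout is completely at random within response group; availability counts
  for the two follow-ups are drawn independently (the published per-group
  counts are not nested).
- Diffusion-type pre-treatment features are truncated below at 0 and α at
  (0.01, 1]; Δ features are untruncated since they legitimately span
  negatives.

Consequently, a passing suite shows the *machinery* is correct under
realistic marginals and noise — not that the effect sizes would replicate in
new patients.

## Statistics

**Group comparison.** Each feature/timepoint is screened per group with
Shapiro-Wilk (supported n: 3–5000; constant samples are flagged non-normal
with p = 0). If both groups pass at 0.05, an equal-variance independent
t test is used, otherwise the Wilcoxon rank-sum (Mann-Whitney) test with
exact small-sample p-values where tie-free. 2×2 tables use chi-square
without continuity correction, switching to Fisher's exact test when any
expected count < 5.

**ROC.** The empirical AUC is computed by the trapezoidal rule over all
observed thresholds; this equals Mann-Whitney pair counting with half credit
for ties, and both routes are implemented and cross-checked exactly. The
AUC variance is DeLong's placement-value estimator; the 95% CI is the normal
approximation clipped to [0, 1], and the AUC p-value is a two-sided DeLong
z test of AUC = 0.5 (the package labels it as such, since other choices
exist). Predictor orientation is fixed from the sign of the group-mean
difference, so reported AUCs are ≥ 0.5 with the direction recorded. The
Youden cutpoint maximizes J = sensitivity + specificity − 1 over observed
thresholds under the rule "value > t" (after orientation); ties resolve to
the larger sensitivity, then the smaller threshold — deterministic by
construction. Paired AUCs are compared with the paired DeLong covariance.

**Multiplicity.** Bonferroni within families: 21 comparisons for DWI
variables (7 features × 3 timepoints → 0.05/21, displayed 0.0024) and 6 for
CE variables (→ 0.0083). Decisions use the exact quotient; display rounds
to 4 decimals.

## Response model

Mid-treatment imaging changes are dichotomized at their Youden cutpoints
(boundary value goes to the reference category, matching the ">" vs "≤"
convention); clinical covariates are coded with the response-enriched level
as 1. Univariate logistic regressions screen candidates at p < 0.05;
backward stepwise selection then removes, one at a time, the variable with
the largest Wald p ≥ 0.05 (Wald rather than likelihood-ratio, matching the
per-variable p-values the model reports). Odds ratios are exp(coef) with
Wald 95% intervals. Fitting is unpenalized maximum likelihood (statsmodels,
Newton); complete separation is detected and flagged on the result — the
coefficients from a capped quasi-Newton fit are retained so predictions
remain usable, but no silent regularization is applied, and separated
variables are not treated as stepwise candidates.

Leave-one-out cross-validation refits the retained model n times and calls
the held-out subject positive at posterior probability ≥ 0.5 (the cutoff is
configurable; a training-fold-Youden alternative was considered and left
out to keep folds cheap and the decision rule transparent). Folds with
single-class training outcomes are skipped and counted. The minimum
supported n is 8, the smallest size at which per-fold fits with one
predictor remain well-posed and exhaustively checkable.

## Pipeline determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded per run; the
CLI's `run-all` writes uncompressed NIfTI and fixed-format CSV, so two runs
with one seed are byte-identical (the manifest records a digest over all
outputs; its own timing fields are excluded from that digest). The default
end-to-end run uses a 24×24×6 two-region phantom (~600 tumor voxels) and a
144-patient cohort, sized so a full run completes in well under a minute on
one core; phantom Monte-Carlo tests use 200 replicates, and the binormal
AUC reproductions use 2000 replicates, at which the replicate-mean AUC has
a standard error below 0.002.

## Known limitations

- No image registration, motion/eddy correction or segmentation: masks must
  share the source grid, and post-treatment ROIs for vanished lesions are
  the user's responsibility.
- The in-plane longest-diameter convention assumes axial acquisitions; a 3D
  mode exists behind a flag.
- D* from IVIM is high-variance by nature at clinical SNR; the package
  reports it (with dispersion visible in Monte-Carlo tests) but sets no
  accuracy bound on it.
- Tissue D from the IVIM fit is computed as a diagnostic but is not part of
  the default reported feature set, which follows the seven-parameter
  convention (ADC variants, D*, f, DDC, α).
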