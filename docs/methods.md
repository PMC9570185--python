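# Methods

## Conditional likelihood for 1:1 matched pairs

All fitting is based on the conditional logistic likelihood.  For pair *i*
with covariate vectors `x_case` and `x_control`, conditioning on the pair
containing exactly one case gives

    L_i(β) = exp(β·x_case) / (exp(β·x_case) + exp(β·x_control))
           = σ(β·z_i),     z_i = x_case − x_control.

The model therefore has no intercept, and any covariate shared within a pair
(the matching factors, or an analyte with identical values in both members)
drops out of the likelihood; its coefficient is fixed at zero by convention.
The penalized estimator maximizes

    Σ_i log σ(β·z_i) − λ1‖β‖₁ − λ2‖β‖₂².

`z` is computed on standardized log concentrations, so exp(β_j) is the odds
ratio per 1-SD increment of log concentration of analyte *j*.

### Solver

The composite smooth-plus-L1 objective is minimized by monotone FISTA
(proximal gradient with Nesterov acceleration, backtracking on the step
length, and a non-increase safeguard so the objective trace is monotone).
Convergence is declared when the relative objective change falls below
`tol` (1e-8 for final fits, 1e-6 inside cross-validation and bootstrap
loops); the iteration cap is 10⁴ and non-convergence is flagged on the
returned fit, never silent.  When `λ1 = 0` the objective is smooth and the
FISTA solution is polished by damped Newton iterations to gradient-level
accuracy (‖∇‖∞ < 1e-11), which is what makes unpenalized fits agree with an
independent maximizer to ~1e-7 in the coefficients.  The hot loop is
JIT-compiled with numba; a pure-Python path exists if numba is unavailable.

Exactly collinear columns of the difference design (equal or negated) leave
the L1 objective indifferent to how weight is split among them, and the
proximal solver splits it evenly.  `fit_signature` therefore canonicalizes
the support after fitting: each exactly-collinear group is pooled onto one
representative (an appended clinical covariate wins over an analyte,
otherwise the earlier column), leaving the fitted linear predictor unchanged
while keeping the reported support minimal and deterministic.

### Penalty tuning

The elastic-net grid is data-driven: `λ1_max = ½·max_j |Σ_i z_ij|` is the
smallest L1 weight that zeroes every coefficient at β = 0; the L1 grid runs
geometrically from `λ1_max` down to `0.08·λ1_max` (5 points), crossed with
`λ2 ∈ {0.5, 4}`.  Including `λ1_max` itself keeps the *null model* on the
grid, which matters on noise: cross-validation can then prefer an empty fit.
The winner maximizes the mean held-out conditional log-likelihood over folds
of pairs (pairs are never split); ties go to the sparser model (larger λ1,
then larger λ2).

Inside a bootstrap replicate the CV folds are built on the *original pair
identities*, so all resampled copies of a pair share a fold.  Without this
grouping, duplicated pairs appear on both sides of a split, the held-out
score rewards overfitting, and the tuning systematically under-penalizes —
on signal-free data this inflated the false-candidate rate badly (in our
null simulations, from 0 candidates in 20/20 seeds with grouping to only
5/20 clean seeds without it).

## Stability selection

Each of `n_boot` resamples draws pairs with replacement (size = original
pair count), re-tunes the penalty by 3-fold grouped CV over the coarse grid,
fits, and records the nonzero support.  Selection frequency is the fraction
of *successful* replicates selecting the analyte (failed fits are excluded
from the denominator and counted); candidates are analytes at or above the
threshold (default 0.80).  Defaults are `n_boot = 350` for release-quality
runs and 100 where turnaround matters; the threshold and grid are
configuration.  The resampling unit is the matched pair because resampling
individuals would break the conditional likelihood.

The analytical robustness filter is pure configuration with a published
default: a candidate is set aside if its catalog entry flags storage
instability or interlaboratory variability, or if its imputed fraction
exceeds 0.5.  Candidates without metadata pass with a warning — never a
silent exclusion.

## Scoring and evaluation

The refined signature is a pure-LASSO (λ2 = 0) conditional logistic fit on
the candidate union, with λ1 tuned by 5-fold CV over pairs.  The OxyScore
`σ(B·X)` is computed per subject on standardized log concentrations.
Because the conditional model has no intercept, the OxyScore is a *relative*
index, not a calibrated probability; the 0.5 classification cut (used for
the error rate) inherits this caveat and is configurable.

Cross-validated performance refits the model within each of k = 10 folds of
pairs (same tuning policy) and pools out-of-fold scores; AUC is the
Mann–Whitney rank statistic with ties counted ½, the 95% CI is DeLong's.
Transfer evaluation applies the frozen coefficients to the second cohort
with *no* refitting; by default the external cohort is standardized with its
own internal location/scale (a deliberate choice — absolute concentration
levels differ between laboratories, and within-cohort standardization
removes that shift; applying discovery parameters instead is available via
`log_standardize(matrix, params)`).

Confidence intervals for per-analyte odds ratios come from an unpenalized
conditional-logit refit on the selected support with Wald intervals; this
post-selection approximation understates selection uncertainty, and the
interface leaves room for a selective-inference replacement.

## Preprocessing

Fixed order: impute → (optional total-signal adjustment) → natural log →
per-analyte standardization.  Non-detects are treated as left-censored and
imputed at half the analyte's minimum observed value; all-missing analytes
are dropped with a warning and the per-analyte imputed fraction feeds the
robustness filter.  The optional per-subject total-signal adjustment
(dividing each subject's values by their summed concentration over the
panel) exists to damp between-subject differences in overall oxylipin load;
it is off by default because quantified panels arrive with varying upstream
normalizations and the step should be an explicit analyst decision.
Cross-cohort harmonization matches analyte names exactly after
canonicalization (case, separators, and the epoxy/Ep spelling variants), so
`9(10)-Ep-stearic acid` and `9(10)-epoxy-stearic acid` merge.

## MetS criteria and severity score

Threshold senses are applied verbatim: waist ≥ 94 cm (men) / 80 cm (women),
TG ≥ 150 mg/dL, HDLc < 40/50 mg/dL, SBP ≥ 130 or DBP ≥ 85 mmHg, glucose
≥ 100 mg/dL; boundary values satisfy criteria.  Medication flags
(triglyceride-, blood-pressure-, glucose-lowering) force their criterion.
The severity z-score `Y + a·waist − b·HDLc + c·SBP + d·log TG + e·glucose`
uses coefficients keyed by sex/ethnicity/age group supplied as a CSV; the
shipped table is a synthetic placeholder scaled to put typical European
adult control/case profiles near −0.7/+0.7, to be replaced by output of the
external severity-score calculator for real analyses.  The log base for TG
defaults to natural log and is configurable.  DBP enters the case definition
but not the z-score — the formula is implemented exactly as specified.

## Synthetic cohorts

The generator emulates the *structure* the analysis assumes, with defaults
fixed at the study conditions used throughout the tests:

- **Cohorts**: 137 and 101 pairs; panels of 88 and 58 analytes overlapping
  in 54 named analytes from the packaged oxylipin catalog; 5 shared signal
  analytes at a 0.8 SD case-control shift in log concentration.
- **Latent severity**: one scalar per subject drives both the criteria and
  the signal analytes.  Cases draw severity from N(0.55, 0.5²) (placed so
  the expected case criteria count is ≈ 3.6); controls from N(μ_c, 0.3²)
  with μ_c ∈ {−1.5, −0.75, 0} by their balance stratum.  Each criterion is
  exceeded with probability σ(slope·(severity − offset)), offsets ordered so
  waist is the most prevalent criterion and low HDLc the least; rejection
  sampling (bounded, with explicit failure) enforces case counts ≥ 3 and the
  exact control stratum, and clinical values are drawn from truncated
  normals on the correct side of each threshold with means/SDs typical of a
  middle-aged European cohort.
- **Concentrations**: log-concentrations are multivariate normal with
  block-diagonal correlation (default: blocks of 6 at ρ = 0.5, a stand-in
  for shared-pathway co-regulation), per-analyte log-means drawn once from
  N(1, 1) (median ≈ 2.7 nM).  Signal analytes add
  `effect × noise_sd × standardized severity`, where the severity is mapped
  affinely so case and control means sit at ±½ — the case-control shift is
  then `effect` SD units, and the signature score inherits a realistic
  correlation with the severity score (Spearman ≈ 0.6–0.7 at defaults).
- **Missingness**: left-censoring of the lowest 5% per analyte (non-detects
  are concentration-driven); the fraction is configurable including zero.
- **Matching**: sex, age class (2-year), smoking, activity (and season /
  menopause labels) are shared within pair.  Medication flags default to
  false so labels are fully determined by the generated values.

What the generator does **not** emulate: instrument drift and batch
structure, diet covariates, m:n matched sets, analyte-specific missingness
mechanisms other than left-censoring, and real oxylipin co-regulation
networks (blocks are a caricature).  Passing recovery tests on these
cohorts therefore demonstrates the statistical machinery under the assumed
structure, not performance on any real population.

## Test/problem sizes

The simulation-based checks use 137/101-pair cohorts with 100 bootstrap
resamples per selection, 10 seeds for recovery medians and 20 for the null
control — sizes chosen to keep the full suite under a minute on one core
while leaving Monte-Carlo margins well away from the asserted bounds.
Closed-form and oracle checks (Newton/BFGS conditional-likelihood maximizer,
exhaustive sign enumeration for the signed-rank test, brute-force
concordant-pair AUC, BH step-up) run at small n where exhaustive computation
is exact.

## Known limitations

- The OxyScore is uncalibrated (no intercept); error rates at the 0.5 cut
  are sensitive to cohort composition.
- Wald CIs on refit support ignore selection; selective inference is out of
  scope but the interface accommodates it.
- Only 1:1 matching is supported.
- The robustness filter's default flags are conservative placeholders in the
  annotation catalog, not measurements; real analyses should curate them.
- The severity-score coefficient table is a documented placeholder.
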