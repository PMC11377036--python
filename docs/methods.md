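# Methods

This note documents the models implemented in `attnconn`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Stop-signal behavior

A trial table carries type (go/stop), onset, response side, RT, stop-signal
delay (SSD, stop trials only), and a late flag. Derived metrics:

- **ICV** = sample SD / mean of Go RTs, computed over *correct, on-time*
  Go responses only. Omissions have no RT, and error or late responses
  index lapses rather than ordinary timing variability; including them
  would conflate two constructs. The sample SD (n − 1) is used because
  per-subject trial counts are modest.
- **Go errors** for the inclusion rule are wrong-side responses +
  omissions + late responses over all Go trials. Exclusion is strict:
  go-error rate > 20% or mean framewise displacement > 0.5 mm; a subject
  exactly at either limit is retained.
- **SSRT** defaults to the integration method — the p(respond | stop)
  quantile of the Go RT distribution minus the mean SSD — the consensus
  recommendation for staircase designs; the mean method (mean Go RT −
  mean SSD) is kept as an option. Boundary commission rates (0 or 1)
  produce a warning and an `ssrt_reliable = False` flag rather than an
  error. The estimation method is a package choice; SSRT values are not
  treated as reproduction targets.

### Staircase boundary behavior

The tracking rule (+50 ms after a successful stop, −50 ms after a failed
one, delays on a 250–900 ms grid) is designed to hold inhibition success at
50%. When the race equilibrium (mean Go finish − SSRT) sits within a step
of the 250 ms floor, *clamping the staircase state itself* turns floor
failures into self-loops: up-moves and down-moves no longer balance, and
the long-run success rate drops to (1 − P(floor ∧ fail))/2 ≈ 46% for a
Normal(500, 100) race with SSRT 200 ms. The simulator therefore tracks an
unbounded staircase state and clamps only the *presented* SSD: every
presented delay stays on the grid, up/down moves balance exactly, and the
long-run success rate is the designed 50%. The hard-clamped variant is
available as `hard_clamp_state=True` and its bias is itself under test.

## gPPI connectivity

Per ordered ROI pair, OLS of the seed series on: intercept; the partner
("physiological") series; HRF-convolved condition boxcars (three for the
go-trials model — go, successful stop, failed stop; two for the
successful-stop model, with go as implicit baseline); PPI terms; the
36-column nuisance block; and discrete-cosine drift columns for a 128 s
high-pass cutoff (`floor(2·T·TR/128)` columns). The edge value is the
PPI(go) coefficient for the go model and PPI(successful stop) for the stop
model — a condition-specific coefficient, not a contrast — because the two
matrices are defined per condition model. The seed×source matrix is
averaged with its transpose and the diagonal zeroed.

- **HRF**: canonical double-gamma (peak 6 s, undershoot 16 s, unit
  dispersions, 1:6 ratio, 32 s support), sampled at TR/16, unit peak.
- **Deconvolution**: the neural signal is represented on a full
  discrete-cosine basis at the TR grid and obtained as the ridge-
  regularized inverse of the HRF convolution operator, with the ridge
  weight chosen by generalized cross-validation over a log-spaced grid
  (1e−12…1e2). The SVD depends only on (T, TR, HRF) and is computed once
  per run, so deconvolving all ROIs is cheap. The round trip
  reconvolve(deconvolve(y)) reproduces smooth noiseless input to < 5%.
- **Nuisance**: 9 base signals (3 translations, 3 rotations, WM/CSF/GM
  means) + backward-difference derivatives (first sample 0) + squares of
  those 18. Derivatives are differenced before squaring, matching the
  common 36-parameter recipe.
- Nuisance and drift columns enter each pair GLM directly (single-stage);
  a two-stage pre-residualized variant is not the default because the
  single-stage model keeps degrees-of-freedom accounting explicit.
- The whole matrix costs `n_roi` least-squares solves, not `n_roi²`:
  all seeds sharing a source are solved simultaneously.

**Identification limits.** Under a dense SST schedule the PPI(go) regressor
is ~99% collinear with the physiological + other PPI regressors, which
puts a floor of roughly 0.4–0.8 on single-subject per-edge noise at
desk-scale run lengths regardless of signal amplitude (source strength and
receiver residual scale together). Planted-coupling detectability is
therefore demonstrated on group-averaged matrices — the form in which
these matrices are consumed downstream — while pair-level recovery is
exact at zero noise and unbiased under white noise.

## CPM

Within each training fold: per-edge partial Pearson correlation with the
phenotype (double residualization against an intercept + covariates;
p from t with df = n − 2 − k), selection at p < 0.01 split by sign,
network strengths by summation (combined = positive − negative), OLS
phenotype ~ strength + covariates. Held-out predictions use the
training-frozen coefficients, including the covariate slopes (refit-free
prediction is the default; a strength-only variant is available).
Performance is the mean over repeats of the per-repeat predicted-observed
Pearson r (not pooled predictions). Covariates: age, sex, mean FD, site
one-hot dummies against a reference level, and mode-centered pubertal
stage at wave 1 when present.

- **Leave-site-out** CV drops the site dummies (a held-out site's dummy is
  unidentifiable in training) and uses the site partition as folds.
- **Consensus** is reported at two levels: edges selected in ≥95% of all
  folds (the mask used for recovery claims), and edges meeting the
  within-repeat 95% rule in ≥48 of 50 repeats.
- **Permutation inference** shuffles the phenotype vector against the
  connectomes and re-runs the full CV pipeline; p = (1 + #{null r ≥
  observed}) / (n_perm + 1), one-sided because predictive skill is
  directional. Covariates stay with the connectomes under the shuffle.
- **Transfer** freezes masks and coefficients from a full-sample model at
  the source wave; target-wave covariate values are pushed through the
  frozen slopes, and significance comes from shuffling the *predicted*
  values. The external-cohort variant correlates covariate-residualized
  strength with the phenotype instead.
- Determinism: every stochastic step draws from `numpy.random.default_rng`
  seeded explicitly; identical seeds give byte-identical outputs.

## Association grids and trajectories

Measures and factor scores are residualized per wave (age, sex, site
dummies; mean FD for brain/behavioral measures only; pubertal stage at
wave 1), then correlated by tie-aware Spearman rank correlation for every
wave pair on the complete-case overlap (no imputation; minimum overlap
20). BH-FDR (q = 0.05) is applied within families — by default one family
per measure grid, mirroring per-panel reporting; the family map is an
argument. Quintile trajectories rank subjects on a baseline measure into
five groups (sizes within 1), with normal-approximation 95% CIs for
display; the High/Low attention labels flip with measure polarity because
higher negative-network strength corresponds to *lower* ICV.

## Substance-use factor analysis

Items are screened (SD ≈ 0 dropped; iterative per-item KMO < 0.5
dropped), Bartlett's sphericity is χ² = −(n − 1 − (2p+5)/6)·ln|R| on
p(p−1)/2 df, extraction is principal-component on the correlation matrix
with the Kaiser eigenvalue-greater-than-1 retention rule (configurable),
rotation is varimax with Kaiser normalization, and scores use the
regression method on standardized items (mean 0 by construction).

The varimax implementation is the classic pairwise algorithm with the
closed-form planar angle per factor pair, swept to convergence. The
popular SVD-based update and the gradient-projection rotation in
statsmodels can stall on exactly symmetric loading patterns (a saddle of
the criterion); the pairwise form does not, and the test suite checks the
rotated criterion against a brute-force angle grid and against statsmodels
on generic inputs.

## Bivariate latent change score model

Single indicators with unit loadings make the three-wave bivariate LCS
equivalent to a path model on the six observed scores; self-feedbacks and
cross-lagged couplings (γ1: substance → Δattention; γ2: attention →
Δsubstance) are constant across transitions, while change intercepts and
residual (co)variances are free per transition and the wave-1 moments are
free. That gives 19 parameters against 27 moments (8 df), the minimal
identified structure with meaningful fit indices. Residual-variance
equality across waves is deliberately off.

- **Estimation**: minimize F = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p +
  (m−μ)'Σ⁻¹(m−μ) by L-BFGS-B with variance bounds at 1e−8; the first
  start is data-driven (pooled OLS of the observed change regressions),
  further restarts (default 5) jitter it by 10%. Non-PD Σ returns a large
  penalty; non-convergence across restarts raises with best-so-far
  diagnostics.
- **Inference**: χ² = (n−1)·F_min; SEs from the inverse numerical
  information ((n−1)/2 × Hessian of F, central differences); Wald
  p-values; standardized coefficients via model-implied SDs of the
  predictor and of the change score (first transition), which makes them
  invariant to rescaling any observed variable.
- **Fit indices**: CFI against the closed-form independence baseline
  (free means and variances; F_base = Σ ln s_ii − ln|S|, df 15); RMSEA =
  √(max(χ²−df,0)/(df(n−1))); SRMR over the 21 standardized covariance
  residuals.
- **Covariates** (age, sex, site) are regressed out of each observed score
  per wave with means preserved before fitting — a two-step scheme chosen
  over covariate paths inside the model for simplicity; at the sample
  sizes involved the point estimates agree.
- **Battery**: every substance × attention pair (canonically 2 × 5 = 10
  models); BH-FDR across the battery's 20 lagged-effect p-values (the
  family choice is this package's, documented rather than asserted as
  canonical). Single-model failures are recorded per cell and the battery
  continues.
- Complete-case estimation; no FIML.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analyses assume —
not scanner physics. Defaults define the study conditions:

- 200 subjects × 60 ROIs (desk scale; 268 ROIs supported), 3 waves, 8
  sites with balanced assignment.
- A latent attention trait per subject follows an AR(1) across waves with
  adjacent-wave correlation 0.5; ICV is an affine readout (trait
  correlation 0.8) calibrated per wave to means/SDs 0.234/0.038,
  0.224/0.051, 0.217/0.052; ages and mean FD (lognormal) match the same
  cohort table; pubertal stage is an integer score mode-centered at
  wave 1.
- 20 positive + 20 negative planted edges load on the trait so that the
  marginal edge–ICV correlation is ≈0.3; all edges carry unit noise and
  per-site offsets (SD 0.2), exercising the covariate control. The
  ground-truth record includes the planted masks and the generative
  ceiling r* (correlation of true-mask combined strength with the
  phenotype after site removal), so recovery claims compare against a
  computable ceiling.
- Substance-use factors follow the LCS generative equations against the
  attention trait (default γ2 = 0.12, γ1 = 0, self-feedback −0.3); TLFB
  counts are rounded lognormal transforms of the factors (heavy tails,
  exact zeros), with tobacco/cannabis items on one factor, alcohol items
  on another, and hard-drug items (waves 2–3 only) on a third. When
  γ1 ≠ 0 the generator also returns the coupled attention series built
  from the cohort's stored innovations; at γ1 = 0 it coincides exactly
  with the traits behind the cohort's ICV and edges.
- The BOLD forward model plants condition-gated couplings using the same
  neural-level construction the estimator assumes, built from the
  *observed* source series; planted coefficients are therefore identified
  without attenuation, exactly at zero receiver noise and unbiasedly under
  white noise.
- Every generator is a pure function of (config, seed): runs are
  bit-for-bit reproducible.

What passing tests on this generator do **not** show: robustness to
physiological noise, spatial autocorrelation of the parcellation,
scanner-specific spectra, non-Gaussian RT distributions, missingness, or
measurement non-invariance across waves — none of which the generator
emulates.

## Problem sizes used in tests

The suite runs the full CPM cross-validation at the default cohort scale
(200 × 60 ROIs, 10-fold × 50 repeats), permutation calibration on 200 null
mini-cohorts (60 subjects, 300 edges, 199 permutations each), LCS recovery
over 100 seeds at n = 1000, and gPPI recovery over 100 simulated pairs —
sizes chosen so the whole suite completes in a few minutes on one CPU
while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Single-subject gPPI edge estimates are noisy at desk-scale run lengths
  (see "Identification limits"); group aggregation or long runs are
  required for edge-level claims.
- The LCS fitter is specific to the 3-wave bivariate structure; it is not
  a general SEM engine (no FIML, no multiple groups, no measurement
  models beyond unit loadings).
- The integration-method SSRT inherits the race model's assumptions and
  is biased when the staircase spends substantial time against the SSD
  grid floor.
- BH-FDR family composition for the association grids and the LCS battery
  is a documented package default, configurable by the caller.
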