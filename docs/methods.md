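# Methods

This note documents the models, the synthetic data the pipeline is tested
on, the numerical choices, and the places where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The latent surface and what the indices estimate

All four indices are *relative* abundance proxies for a latent expected
count per standardized survey unit,

λ[s, g, t] = exp(β₀ₛ + bₛg + τₛ·(t − t̄)),

for species s, town g, year t, with t̄ the mid-study year. τₛ is the exact
log-scale annual trend in every town; bₛg ~ N(0, σ²_town) shifts town
levels. None of the indices estimates λ on its own scale — a detection
probability saturates as λ grows, and checklist balancing shifts the
detection odds — so the pipeline's claims are about *correspondence*:
monotone agreement of annual series, agreement of proportional year-over-
year changes, and recovery of the trend direction.

## Synthetic surveys

The generator emulates the statistical structure of the two stream types:

* **Checklists.** Each survey draws a town (Dirichlet "hotspot" weights), a
  location within town, an observer from a pool of 60 with log-scale skill
  spread σ_skill = 0.4, a date in the breeding window (day 121–196), start
  time (morning-biased Beta(2,4)), protocol (30% stationary / 62% traveling
  / 8% random), duration ~ logN(log 0.9, 0.6) h, distance ~ logN(log 1.5,
  0.8) km, party size 1 + geometric. Detection is Poisson thinning,
  p = 1 − exp(−λ·E·e^skill), with the log-linear effort multiplier
  E = (dur)^0.7·(1+dist)^0.3·party^0.2, so detection is monotone in λ and
  in each effort covariate. List length is a background community drawn per
  checklist with mean 12·E^0.4 from an 80-species pool, plus the focal
  detections — effort and list length are correlated the way the effort-
  proxy argument requires. A few percent of records violate each filter
  (incomplete, overlong, over-distance, oversized party, out of season) so
  filter tests are meaningful.
* **Routes.** Each route sits in one town and is run once per year by a
  mostly persistent observer (10% annual turnover); counts per stop are
  Poisson with mean `stop_scale`·λ (default 0.2 — a stop samples a smaller
  area than a checklist), optionally negative-binomial to exercise the
  quasi-Poisson fit; 5% of runs carry a low-quality flag.

Default study conditions (the `Scenario` dataclass): 5 towns, 14 years
(2005–2018), ~3,000 checklists in total with unequal annual counts
(multinomial over a Dirichlet(8) year distribution), 10 routes × 50 stops,
base rate 0.6 expected focal birds per standardized checklist, town sd 0.3,
trends ±0.2/yr alternating across 20 species.

What the generator does **not** emulate: geographic coordinates and polygon
geometry, within-season phenology curves, migration, taxonomic structure
(sub-species mapping is an identity here), observer learning over years,
and spatial autocorrelation beyond the town level. Passing tests therefore
show the pipeline's statistical machinery is correct and well-calibrated on
data with the right moment structure; they do not certify behavior on real
extracts with richer spatial texture.

## Preprocessing

Filters follow the standard effort envelope (≤ 10 in the party, ≤ 5 h,
≤ 5 km, stationary/traveling protocols after reclassifying "random" by
distance, complete lists only, May 1 – Jul 15, ≥ 5 species). Group
duplicates merge to one unit whose species set is the union. Range
restriction keeps survey locations (checklists) or routes (stops) with at
least one detection of the focal species in the study period. Zero-filling
emits exactly one row per survey unit; day of year and start time are
centered over the table being analyzed, and the centering means are stored
and reused for prediction grids.

Balancing runs three stages with a fixed seed: (1) keep at most one
detection and one non-detection per (town cell, year, season-week) stratum;
(2) subsample non-detections to at most 4 per detection; (3) downsample
each year's non-detections toward the smallest annual sample within a 25%
tolerance. Detections are never dropped after stage 1. A consequence worth
knowing: when annual sample sizes differ, stage 3 changes the per-year
detection:non-detection ratio unevenly, which adds year-to-year distortion
to the checklist GLMM index (the case-control offset varies by year). That
is inherent to "retain detections preferentially" year balancing; the
low-noise concordance test therefore uses equal annual effort, where the
distortion vanishes.

## The mixed-model engine

Binomial (logit) and quasi-Poisson (log) GLMMs with crossed random
intercepts are fitted in the nAGQ = 0 regime: for candidate random-effect
standard deviations θ, fixed effects β and spherical modes u are optimized
*jointly* by penalized IRLS, and the profiled Laplace criterion
dev(y, μ) + |u|² + log det(Λ'Z'WZΛ + I) is minimized over log θ by
Nelder–Mead. Agreement with `lme4::glmer(..., nAGQ = 0)` is checked in the
test suite (fixed effects to ~1e-6 on a 600-row crossed fixture).

Numerical choices:

* inner PIRLS stops on coefficient change < 1e-8 or a sustained penalized-
  deviance plateau (4 iterations below 1e-10 relative change) — the plateau
  rule is needed because quasi-separated sparse cells (e.g. a year with no
  detections in one class) drift at flat deviance; step-halving guarantees
  the penalized deviance never increases;
* outer Nelder–Mead uses xatol 1e-4 on log-sd and fatol 1e-6 on the
  criterion; fitted sds below 1e-4 collapse to exactly zero and the model
  is re-profiled, so zero-variance data reproduce the plain GLM to machine
  precision;
* complete separation is reported as an error only when boundary
  coefficients (|β| > 25) coincide with a near-perfect fit (deviance
  < 0.05 n); otherwise boundary cells are tolerated as lme4 tolerates them;
* quasi-Poisson dispersion is φ = Pearson χ²/(n − p) with p the number of
  fixed effects (random-effect df are not subtracted), and scales all
  fixed-effect covariances;
* the year factor's reference level is the first study year; standardized
  predictions are invariant to that choice.

Standardized prediction uses the species' modal detection day of year and
start time (empirical mode over detections, hour-binned for start time),
the species' mean list length, traveling protocol, the town's conditional
mode, and observer effect zero. The same grid convention serves both
checklist engines so their indices are comparable.

Bootstrap SEs are parametric: simulate responses from the fitted model
(random intercepts redrawn), refit, re-predict the grid; the SE is the
sample sd over B replicates, requiring ≥ 0.8 B successful refits.
Quasi-Poisson simulation draws Poisson at μ̂ — quasi-likelihood has no
generative model, and φ enters analytically, not in simulation. Defaults:
B = 200 with full re-optimization of θ. Batch pipeline runs (the analysis
scripts, the multi-species studies in the tests and the acceptance script)
use B = 40 with θ held at its fitted value, a standard large-batch
compromise: θ's sampling variability contributes second-order terms to a
prediction SE that is only used as an aggregation weight.

## The balanced random forest

500 trees (300 in batch runs) on predictors (year, day of year, start
time, list length, town), each grown on a bootstrap that downsamples the
majority class to the minority count; `min_samples_leaf = 5`; score = vote
fraction. Calibration regresses the observed 0/1 response on *out-of-bag*
vote means with a binomial B-spline GAM (df 10) — in-bag votes memorize the
training labels and separate the GAM — with a ridge-penalized fallback if
separation still occurs, and the curve is clamped to [0, 1] and the trained
score range. Evaluation on the held-out 20%: Mann–Whitney rank AUC with tie
correction, Cohen's kappa maximized over a 101-point threshold grid, MSE
against the 0/1 outcome before and after calibration. The prediction SE is
sd(votes)/√T floored at 1e-4 so unanimous forests keep finite inverse-SE
weight.

## Aggregation and comparison

State aggregates use the stated weights w = 1/SE (not inverse variance —
deliberately, since the weighting is defined that way), with SE propagated
as √(Σ w²SE²)/Σ w. Inter-annual change is undefined (missing, logged) when
the previous estimate is zero. The trend model is a Gaussian GLM on the
z-scored index with centered year + year² and Wald 95% CIs — a binomial GLM
cannot take z-scored responses, so the Gaussian form is the coherent
resolution; constant series report a zero trend with a warning. The
Shapiro–Wilk gate (p < 0.05 on either vector) switches state correlations
from Pearson to Spearman; p-values use the t transform; no multiple-testing
correction is applied, matching the raw-reporting convention of this
analysis style. Town-level pairs use weighted Pearson with the product
rule w_t = 1/(SE_a,t·SE_b,t). The spatial regression is a Gaussian LMM
(species random intercept) of town-level r on scaled-centered survey
density and habitat proportions; with fewer towns than covariates the
design is unidentifiable and the function refuses it (the 5-town demo uses
a two-covariate subset), and a single species or constant response falls
back to OLS with a warning. LOESS with span 2 (all points, tricube
bandwidth inflated by the span) is provided for figures only.

## Problem sizes

The test suite and acceptance script size their simulations to run on one
CPU in a few minutes: the 20-species trend-recovery study uses the default
scenario above (~140 s); the noise-dominated regime uses 5 scenarios of 4
species with 700 checklists, 4 routes, trend ±0.12, σ_skill = 1.0 (~120 s);
oracle checks use n = 2,000–20,000 single fits. Monte-Carlo tolerances are
3 simulation SEs unless an exact identity is being asserted (1e-6–1e-12).

## Known limitations

* The nAGQ = 0 criterion underestimates random-effect variances slightly
  relative to full Laplace or adaptive quadrature; this matches the target
  fitting regime by construction but is not a general-purpose GLMM.
* Detection probability saturates for abundant species (λ·E ≫ 1), which
  compresses trends near the top of the scale; the count index does not.
* Case-control balancing biases the detection index's *level*; all
  downstream statements are correspondence statements, not absolute
  detection probabilities.
* Bootstrap SEs treat refit failures as missing at random (requiring 80%
  success); severely separated data will fail loudly rather than silently.
* The spatial regression inherits the usual caveats of habitat-proportion
  covariates: compositional, collinear in small town sets, and here purely
  synthetic — it demonstrates estimator calibration, not ecology.
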