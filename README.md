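# birdindex

Annual relative-abundance indices from heterogeneous bird-survey streams,
and a framework for asking how far you can trust them at fine resolution.

## The problem

Community-science checklists (semi-structured surveys with wildly varying
effort) and structured route-stop surveys (fixed transects run once per
year) both carry a signal about how bird populations change. Multi-year
trends derived from the two stream types tend to agree at coarse regional
scales, but many applications — linking populations to local disturbance,
habitat change, infrastructure — need *annual* estimates and *year-over-year
changes* inside small administrative units. This package implements the full
comparison pipeline: it builds four annual indices of relative abundance per
species and quantifies their correspondence at three temporal resolutions
(multi-year trend, annual estimate, inter-annual change) and two spatial
scales (region, town).

The four indices, on a common (species, town, year) frame:

| Index | Stream | Model |
|---|---|---|
| checklist GLMM-DP | checklists | binomial mixed model, detection probability |
| checklist RF-DP | checklists | balanced random forest + GAM calibration |
| route DP (`BBS-DP`) | route stops | binomial mixed model, detection probability |
| route RA (`BBS-RA`) | route stops | quasi-Poisson mixed model, counts per stop |

Because real survey extracts are large and access-restricted, the package
ships a synthetic survey generator with a known latent abundance surface
λ\[s, g, t\] = exp(β₀ₛ + bₛg + τₛ·(t − t̄)), so every stage — filters,
balancing, model fits, aggregation, comparison statistics — can be scored
against ground truth.

## The models

**Checklist detection probability (GLMM).** Checklists are filtered to a
standardized effort envelope (≤ 10 observers, ≤ 5 h, ≤ 5 km, complete,
breeding season, ≥ 5 species), zero-filled to presence/absence, and
spatiotemporally subsampled to balance detections against non-detections
and sample sizes across years. Then

logit P(yᵢ = 1) = year\[tᵢ\] + f(doyᵢ) + γ·startᵢ + (β_L Lᵢ) × protocolᵢ + u_town(i) + u_obs(i),

with f a centered quadratic in day of year, L the list length (the number
of species on the checklist, a one-dimensional effort/skill proxy; the
log-L form is selected per species by likelihood), and crossed Gaussian
random intercepts for town and observer. Fitting profiles the random
effects inside penalized iteratively reweighted least squares (the nAGQ = 0
regime, matching `lme4::glmer(nAGQ = 0)` — verified against it in the test
suite). Predictions standardize a survey: modal detection day and start
time, mean list length, traveling protocol, observer effect zero.
Prediction SEs come from a parametric bootstrap (simulate → refit →
re-predict).

**Checklist detection probability (balanced RF).** Each of 500 trees trains
on a bootstrap with detections and non-detections equalized; the vote
fraction is calibrated against observed detection rates with a binomial
spline GAM and evaluated on a held-out 20% (rank-based AUC, Cohen's kappa
maximized over thresholds, Brier-type MSE before/after calibration). The
prediction SE is the tree-vote standard error.

**Route-stop models.** Counts at each of 50 stops per route run are
expanded with explicit zeros; detection probability (binomial) and relative
abundance (quasi-Poisson, dispersion φ = Pearson χ²/df) use year factors
and town + observer random intercepts only, since the protocol already
standardizes effort.

**Aggregation and comparison.** State series are inverse-SE weighted town
averages, x̂ = Σ w_g x_g / Σ w_g with w = 1/SE. Inter-annual change is
Δ_t = (x_t − x_{t−1})/x_{t−1}. State-level pairs are correlated with
Pearson's r (Spearman when Shapiro–Wilk flags non-normality at p < 0.05);
town-level pairs use weighted Pearson with w_t = 1/(SE_a,t·SE_b,t).
Multi-year trends are Gaussian GLMs of the z-scored index on centered year
plus its square; two indices are trend-consistent when the 95% CIs of
their linear coefficients overlap. Town-level correspondence is regressed
on town attributes (survey density, habitat proportions) with a species
random intercept.

## Worked example

The `analysis/` scripts run the whole study on synthetic data:

```bash
python analysis/01_simulate.py --seed 1      # surveys + latent truth
python analysis/02_preprocess.py --seed 1    # filters, zero-fill, balancing
python analysis/03_fit_indices.py --seed 1   # the four index engines
python analysis/04_assemble_indices.py       # state aggregation, changes
python analysis/05_compare_indices.py        # correspondence statistics
```

With the default six-species scenario (5 towns, 14 years, ~3,000
checklists, 10 routes), the final step prints:

```
trend consistency: 36/36 index pairs consistent across 6 species
annual correlations: mean |r| = 0.87 over 36 pairs
interannual correlations: mean |r| = 0.43 over 36 pairs
trend-direction recovery BBS-DP: 6/6
trend-direction recovery BBS-RA: 6/6
trend-direction recovery eBird-GLMM-DP: 6/6
trend-direction recovery eBird-RF-DP: 6/6
spatial regression (BBS-DP ~ eBird-RF-DP): herbaceous effect 0.011 (-0.002, 0.024); 30 town-species observations, 6 species
```

Read: every index recovers the direction of every species' true ±0.2/yr
trend and the indices agree closely year by year (|r| ≈ 0.87), but
correspondence drops sharply for year-over-year *changes* (|r| ≈ 0.43) —
the resolution-dependent reliability pattern the pipeline is built to
measure. All tables land under `results/`.

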