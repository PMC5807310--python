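# Methods

## The model

Clutch-initiation dates are integer day indices on a fixed 365-day calendar
(day 1 = Jan 1 of the breeding year; November of the previous autumn runs
from day −60). All window analyses fit the same linear mixed model by
maximum likelihood:

    date_ij = x_j' beta + a_j + e_ij,     a_j ~ N(0, s2_year),  e_ij ~ N(0, s2_resid)

where *j* indexes breeding years and every fixed covariate — a climate
window mean, a centred year trend, an annual ecological covariate — is
constant within a year. ML (not REML) is used throughout because AICc is
compared across fixed-effect structures. AICc counts k = p fixed effects +
2 variance parameters against n = records; AICc (not AIC) drives both the
window ranking and the candidate competition, consistent with the ΔAICc ≤ 2
screening rule.

**Fitting.** Because the covariates are year-constant, the ML problem
profiles down to a one-dimensional optimization over the variance ratio
θ = s2_year/s2_resid, with the fixed effects a weighted least-squares fit of
the year means and s2_resid in closed form; sufficient statistics are the
per-year counts, means and the pooled within-year sum of squares
(`phenowin.lmm`). One fit costs O(#years), which is what makes a 20,910
window scan with a 100-randomization guard tractable on one CPU. The scan
path optimizes θ on a 62-point log grid with parabolic refinement; the
scalar path uses bounded Brent with an explicit θ = 0 boundary check. Both
agree with `statsmodels` MixedLM (ML) to ≈ 1e-5 in log-likelihood, which
the test suite checks as an independent oracle; the fitter is never the
cross-check for itself.

**Ties and degeneracies.** The best window is the AICc minimum; ties (at
1e-9) break toward the shorter, then earlier, window. Windows whose fit
fails are excluded from the Akaike weights with a warning. A response with
zero total variance makes R² undefined and raises.

## Backdating, imputation, cross-validation

Backdating treats the first nestling-stage observation as the hatch date
and inverts the laying schedule (incubation is counted from clutch
completion to hatch; actual clutch size where known, species mean
otherwise). The initiation prediction model encodes stage and outcome as
treatment contrasts with the most frequent level as reference (the coding
is not externally pinned down, so the package picks the statistically
neutral default). Cross-validation uses k = 5 disjoint folds stratified by
species with a 20% set-aside each; the RMSPE pooled over all held-out
predictions is the imputation SD. Prediction for a species unseen in
training uses the population intercept (its BLUP is zero); species BLUPs
are computed in closed form (shrunken species-mean residuals), which stays
defined when the species variance is estimated at the zero boundary.
Imputation never perturbs field-observed dates. Annual means and their 95%
CIs (mean ± 1.96·SD/√n) are averaged across 500 imputed datasets; pooling
everywhere uses medians and 2.5/97.5% quantiles of runs, not Rubin's rules,
matching the averaging convention of the analysis this package
operationalizes. Single-nest years are flagged and excluded from
correlation and window analyses.

The scan consumes one imputed dataset (the first draw); imputation
uncertainty enters the *coefficient* stage, where all 100 imputations are
refit. This keeps the window search identical across candidate variables
while still propagating prediction error into every reported interval.

## Randomization guard (design choice)

The guard asks how much AICc improvement over the intercept-only model an
exhaustive scan produces by chance. Two permutation units are implemented.
The default permutes the window covariate **across years**: the covariate
is year-constant, so years are the exchangeable unit, and this null
preserves the response's year-level variance structure while severing the
date–weather linkage. Permuting individual dates across records (the
alternative, `unit="records"`) additionally destroys year clustering, so on
strongly year-structured data its null is lighter than the observed
statistic and the test becomes anti-conservative — measured as an ~85%
spurious-flag rate on no-signal data versus ~95% for the year unit. The
p-value is the empirical rank form (1 + #{S_null ≥ S_obs})/(n_rand + 1);
spurious iff p > 0.05.

## Bootstrap pooling (design choice)

The 100 × 20 imputation–bootstrap ensemble resamples **years** (cluster
bootstrap: years drawn with replacement, each sampled year's records kept
as a distinct pseudo-year). With year-constant covariates the sampling
noise of a coefficient lives at the year level; resampling only records
within years leaves year means nearly fixed and demonstrably understates
the 95% ranges (~70–80% coverage of generating slopes instead of the
measured 92–96%). Within-year (`"stratified"`) and identity (`"none"`)
modes remain available. AICc and R² are pooled as medians across the
*un-resampled* fit of each imputation: information criteria computed on
resamples with duplicated years are biased toward larger models (verified
on trendless data, where the null model otherwise stopped beating a linear
trend model). The Nakagawa-style R² takes the fixed-effect variance over
the record-level linear predictor.

## Synthetic data: what it emulates, and what not

The weather generator produces daily mean temperature as seasonal sinusoid
+ i.i.d. normal calendar-year offsets + AR(1) noise, with max/min as fixed
offsets plus small jitter and exponential daily rainfall. Defaults
(amplitude 12 °C around 4.5 °C, year SD 0.8 °C, AR(1) ρ = 0.65 with
innovation SD 2.5 °C) give an annual window-mean maximum-temperature SD of
≈ 1.5 °C for a 4-week spring window — a realistic interannual spread for an
interior-plateau station.

Species truth makes latent initiation linear in the mean daily maximum
temperature of a fixed window. The default noise partition is anchored to
published community estimates for a mid-spring responder (slope
−2.25 d/°C, marginal R² ≈ 0.18, conditional R² ≈ 0.31): with a 1.5 °C
window-mean SD this implies a year-effect SD near 3 d and a residual SD
near 6.5 d, which the defaults adopt (`year_sd=3.0`, `resid_sd=6.5`). The
observation process forward-simulates laying → incubation → nestling,
discovers the nest at a stage, revisits every 3–5 days, and records the
true initiation date with probability 352/1628 ≈ 0.216.

Not emulated: spatial structure, detection heterogeneity, renesting
dynamics beyond flags, beetle/cavity population dynamics (the ecology table
is a smooth pulse + trends), and any nonlinearity or threshold in the
temperature response. Passing tests therefore demonstrate that the
machinery recovers truth under the stated linear-mixed generating model,
not that real communities satisfy that model.

## Problem sizes in the test suite and acceptance script

Replicate experiments run at 17 years × 20–30 nests with a 3-day scan step
over a Feb 1–May 1 range, 50 randomizations, and 20 × 5
imputation–bootstrap settings; these sizes make each experiment a
seconds-scale computation while keeping the Monte-Carlo error of the
reported rates a few percent. Under these conditions the measured
window-recovery rate (best window Jaccard ≥ 0.5 with negative slope) sits
near 80%, with the characteristic failure mode being a selected window
that contains the truth but is about twice as wide — window-width
uncertainty intrinsic to exhaustive scans over autocorrelated weather.

## Known limitations

- Windows are absolute calendar intervals shared by all nests in a year;
  nest-relative ("biological") windows are out of scope.
- One weather variable per window model; no quadratic or threshold response
  shapes, no interactions, no model averaging.
- Ecological covariates enter at the breeding-year value (no lags).
- The guard's year-permutation null assumes exchangeable years; a strong
  temporal trend in both weather and dates would violate it (the candidate
  competition's trend model is the place such structure is examined).
- The 365-day calendar ignores Feb 29; ISO weather input on leap years
  drops that day and shifts later days back one index.
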