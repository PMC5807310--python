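# phenowin

Community breeding-phenology analysis for resident birds: which calendar
window of local weather best predicts clutch initiation, how certain is that
window, and does a shared weather driver actually synchronize breeding
across species?

The package is aimed at avian ecologists with multi-year nest-record tables
(partially censored clutch-initiation dates), a daily weather-station series
and annual ecological covariates. It implements the full chain:

1. **Backdating & imputation.** Nests found at the nestling stage are
   backdated to an egg-stage date via
   `egg_day = hatch − incubation − (clutch − 1)/lay_rate`. Records with a
   field-recorded initiation date train a linear mixed model (date & stage
   of first activity, last active date, outcome, visit count; species as a
   random intercept) whose 5-fold cross-validated RMSPE calibrates a
   Monte-Carlo multiple imputation: each missing date is replaced per
   dataset by the point prediction plus an independent N(0, RMSPE²) draw.
2. **Sliding-window scan.** For each weather variable every calendar window
   of ≥ 10 days between Nov 1 of the previous year and Jun 1 is scored by
   the AICc of the mixed model `date_ij = β₀ + β₁·w̄_j + a_j + ε_ij` (w̄_j =
   window mean in year *j*, `a_j ~ N(0, σ²_year)`), fit by ML; support is an
   Akaike-weight surface over (open, close) days. A randomization guard
   (permuting the covariate across years, 100 times by default) flags scans
   whose AICc improvement is within chance range (p > 0.05) as spurious.
3. **Model competition.** Surviving weather variables (ΔAICc ≤ 2 of the
   best) are competed against null, linear-trend, and guild-appropriate
   ecological models over 100 imputations × 20 bootstrap resamples;
   reported coefficients are the medians and 2.5/97.5% quantiles of the
   2000 runs, with marginal/conditional R² (fixed-effect vs fixed+year
   variance shares).
4. **Synchrony.** Pairwise Pearson correlations of annual mean dates over
   shared multi-nest years, Benjamini–Hochberg-controlled at FDR 0.05.

A synthetic-data module generates weather (seasonal sinusoid + year offsets
+ AR(1) noise), species with known window/slope truth, and a realistic
observation process, so every stage is testable against ground truth.

## Worked example

Simulate a 3-species, 17-year community and scan one species:

```bash
phenowin simulate --years 1995:2011 --species 3 --nests-per-year 30 \
    --seed 11 --outdir demo
phenowin scan --nests demo/nests.csv --weather demo/weather.csv \
    --life-history demo/life_history.csv --species species_b \
    --variable tmax --start 02-01 --end 05-01 --step 3 --nrand 50 --seed 11
```

prints

```
best window: Mar 27-Apr 11 (width 16 d), slope -2.41, AICc 3392.5, weight 0.061
randomization p = 0.039
```

i.e. the best-supported critical temperature period for this species is
Mar 27–Apr 11: each extra degree of mean daily maximum temperature in that
window advances clutch initiation by ≈ 2.4 days (the generating truth for
this species is −2.47 d/°C in a late-March window), the window's Akaike
weight is 0.061 of the scanned set, and the scan's AICc improvement beats
the year-randomized null (p = 0.039 ≤ 0.05, not spurious).

The lag between a species' critical period and its breeding is summarized
by `phenowin intervals`, which recomputes the published community table —
e.g. the hairy woodpecker's Jan 7–Feb 19 window closes 78 days before its
May 8 mean lay date, the red-breasted nuthatch's Apr 5 close is 53 days
before May 28, the downy woodpecker's May 19 close 12 days before May 31.

The full pipeline (validate → impute → scan all variables → guard →
competition → synchrony → reports) runs from a YAML config:
`phenowin run --config run.yaml`.

As a library, the two model-shaped stages are sklearn-style estimators
(`InitiationModel().fit(records).predict(...)`,
`ClimateWindowScanner(...).fit(dates, weather)` with `best_`, `weights_`,
`randomization_test()`), and each pipeline stage is a plain function.

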