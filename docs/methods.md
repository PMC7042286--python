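# Methods

## Overview

`maizestress` quantifies how much heat and drought stress a maize trial
environment imposed on the crop, and whether a hybrid's yield is stable
under that stress.  The chain is:

1. engineer 26 stage-windowed weather features plus 8 soil descriptors per
   environment;
2. fit a 100-tree random forest predicting environment-mean yield from the
   34 features, evaluated by 10-fold cross-validation;
3. model the joint density of the feature vectors (z-score → PCA at 99%
   explained variance → variational Bayesian GMM) and draw surrogate
   feature vectors from it;
4. for each feature, perturb 500 surrogate rows to each of 11 grid values
   spanning the feature's observed range and record the mean ± SD change in
   predicted yield — the feature-value contribution;
5. sum each environment's nearest-grid contributions over the 12 heat
   features and over the 14 drought features, giving two stress totals in
   quintals/ha of predicted yield change (more negative = more stress), and
   rank environments by them;
6. regress each hybrid's yields on the stress totals of the environments
   where it grew; slopes < 1 with exposure to extreme (bottom-decile)
   environments classify the hybrid as stress tolerant.

## Feature engineering

The growing season `[planting, harvest)` is split at round(0.30·GSL),
round(0.50·GSL) and round(0.75·GSL) days after planting into four windows
anchored on maize phenology (planting→VT, VT→R2, R3→R6, R6→harvest).
Rounding is Python's half-to-even; windows are half-open day-offset
intervals.  A degenerate-rounding guard keeps all four windows non-empty on
pathologically short seasons (it is inert for GSL ≥ 6; real maize seasons
run 150–180 days).

Per window:

| feature | definition | unit |
|---|---|---|
| EDD | Σ max(0, Tmax − 30 °C) | °C·days |
| CTD | longest run of days with Tmax > 30 °C | days |
| CTN | longest run of nights with Tmin > 20 °C | days |
| PS | Σ precipitation | mm |
| CDD | longest run of days with precipitation < 1 mm | days |
| VPD | mean of max(0, es(Tmean) − e_a) / 100 | mbar |
| HTC | ΣP / (0.1 · Σ{Tmean > 10 °C}) , stages 2–3 only | – |

All temperature thresholds are strict.  Tmean = (Tmax + Tmin)/2 since daily
weather carries no mean temperature.  Saturation vapour pressure uses the
Magnus form es = 610.78·exp(17.27 T / (T + 237.3)) Pa; supersaturated days
clamp the deficit to 0 but still count toward the stage mean.  HTC in the
early and late windows is frequently undefined (too cool), so only HTC2 and
HTC3 are features; a residual undefined HTC (no day above 10 °C mid-season)
becomes NaN and is median-imputed across environments before modelling.
Day length, solar radiation and snow water equivalent are read and
validated but produce no features.

## Preprocessing

Rows with unknown irrigation are dropped; rows with harvest ≤ planting are
dropped (equality gives a zero-length season that cannot be stage-split);
missing soil values are median-imputed; replicate (hybrid, environment)
rows collapse to their mean yield.  The pass is idempotent and keeps full
row accounting.  Environment-level fields (dates, irrigation, soil) are
taken as the modal value within the environment, with a warning on
conflicts.

## Yield model

`RandomForestRegressor` with 100 trees, every other hyperparameter at the
library default, seeded.  Cross-validation pools out-of-fold predictions
across the 10 folds and computes R², RMSE and Pearson r on the pooled
pairs (per-fold values are also reported); rows are sorted by index before
fold assignment so the evaluation does not depend on input row order.  Both
an all-environments evaluation and one excluding normally irrigated
environments are produced — irrigation masks drought stress and visibly
changes the attainable R².  The model used for explanation is refit on
all environments after evaluation, maximizing explanation fidelity.

## Density enrichment

Features are z-scored before PCA because their raw units are
incommensurate.  The retained dimension k is the smallest reaching 99%
cumulative explained variance.  The initial mixture size comes from an
EM-GMM scan (full covariances, M = 2…20) taking min(argmin AIC, argmin
BIC), ties toward smaller M.  The variational fit is a
`BayesianGaussianMixture` with a Dirichlet-process (stick-breaking) weight
prior truncated at that M, concentration 1/M, tol 1e-3, max 500 iterations,
covariance regularization 1e-6; surplus components are pruned by weights
collapsing toward zero, and components above a 1e-3 weight floor are
reported as "effective" (sampling uses all weights as fitted).  Surrogates
are drawn with a seeded generator (component indicators, then Cholesky
draws) and back-projected through the inverse PCA/standardization map,
without clipping to observed ranges — downstream nearest-grid lookups clamp
instead.

## Explanation and stress totals

Contribution grids span each feature's observed min–max in the original
(non-surrogate) environment data with 11 equidistant points.  One fixed
draw of 500 surrogate rows (without replacement) is reused across all
(feature, value) tests, which removes between-grid-point Monte-Carlo
jitter; a flag restores independent draws per test.  delta = ŷ(altered) −
ŷ(original); SD uses the sample (n−1) denominator; a contribution is
significant when mean + SD < 0.  Constant features keep a single-point
inert grid contributing exactly zero, preserving the 34-slot layout.

Stress totals look up each meteorological feature's nearest grid point
(midpoint ties to the lower value, out-of-range values clamp) and sum the
mean contributions — significance is not filtered, since small positive
contributions are legitimate parts of the balance.  Ranking is ascending in
the total (rank 1 = most stressed, ties broken by environment id);
extremes are totals strictly below the linear-interpolation 10th
percentile, pooled over all environments (a per-year variant would simply
partition the table first).

## Stability classification

Stress totals grow more negative with stress, so a stress-sensitive hybrid
(yield falling fast as stress deepens) has a large positive slope of yield
on the total, and slope < 1 marks stability — the Finlay–Wilkinson
adaptability reading.  Negative slopes satisfy the literal rule and are
classified tolerant; they are visible in the output for inspection.
Normal-irrigation samples are excluded from all slope fits.  Single-stress
slopes need ≥ 2 environments with distinct totals; the joint two-predictor
fit needs ≥ 3 and a full-rank design, else the hybrid is non-tolerant with
a reason code.  A tolerance label also requires exposure: at least one
growing environment below the 10th percentile of that stress type.
Combined tolerance requires both single labels plus both joint-regression
slopes < 1, which keeps the five summary categories (none / drought only /
heat only / both singles / all three) exhaustive and mutually exclusive.
The irrigated-vs-rainfed contrast per hybrid uses a two-sided Welch t-test
(α = 0.05 reading); when both groups are constant the p-value degenerates
to 1 (equal means) or 0 (shifted means).

## Synthetic trial network

The generator emulates the two input tables with planted ground truth.
Environments sit on two independent axes: a heat axis scaling the summer
Tmax peak linearly from 24 to 38 °C and the humidity factor from 0.92 down
to 0.45 (hot sites have drier air — the dominant pathway by which extreme
heat raises vapour pressure deficit), and a dryness axis scaling wet-day
probability 0.55→0.15 and the Gamma rain scale 8→5 mm.  Daily Tmax is a
sinusoid peaking at day-of-year 200 (amplitude 14 °C) plus AR(1) noise
(sd 3 °C, lag-1 correlation 0.7); Tmin is Tmax minus a positive diurnal
range (mean 11 °C, sd 2 °C, floor 3 °C); precipitation is Bernoulli ×
Gamma(shape 0.8); vapour pressure is the humidity factor times saturation
at Tmean, so a factor of 1 yields saturated air and zero VPD.  Planting
falls 55% into the spring warm-up (day-of-year ≈ 118) and harvest follows
after a 150–180-day season.  One global seed expands to per-entity
substreams, so any environment or hybrid regenerates identically
regardless of order.

Ground-truth stress scores use the same functional families as the
pipeline's features but independent, floor-based stage arithmetic:
S_heat = −(0.05·EDD3 + 0.35·VPD3) and S_drought = −0.12·Σ stage-2/3
precipitation deficits below a 2.5 mm/day crop demand, both in quintals/ha
for a unit-sensitivity hybrid.  Yields follow base + β_heat·S_heat +
β_drought·S_drought + ε with the drought term suppressed under normal
irrigation, ε ~ N(0, 2.5 q/ha), truncation at zero.  Tolerant slopes are
U(0.2, 0.8), susceptible U(1.4, 2.2), base yields ≈ N(110, 8) q/ha, and
irrigation categories follow the renormalized field shares (≈ 76/0.2/1.7/22
% none / very light / light / normal).

Each hybrid is assigned 12 environments spanning both stress axes with a
balanced design: one site from the most-stressed heat decile and one from
the most-stressed drought decile (preferring non-irrigated sites and
near-median positions on the other axis), one per cell of a 3×3
heat×drought tercile grid favouring cell-centre-representative sites, and
random fill.  The balance keeps the two stress totals near-orthogonal
within each hybrid's sites; without it, single-predictor stability slopes
absorb omitted-variable bias from the other stress and planted labels near
the slope-1 boundary become unrecoverable regardless of noise level.

What the generator does **not** emulate: spatial correlation between
sites, real geographies or calendars, multi-year weather persistence, any
phenology beyond fixed stage fractions, soil effects on yield, or
genotype×environment interactions beyond the two linear sensitivity
slopes.  Passing recovery tests therefore demonstrate that the analysis
chain is correct and identifiable under its own assumptions, not that
those assumptions hold for any particular field dataset.

## Problem sizes and numerical choices

The test suite exercises the pipeline on 40-environment/20-hybrid networks
and the acceptance checks on 120 environments × 80 hybrids; the
acceptance script runs 150 environments × 120 hybrids with 10,000
surrogates and 500-row perturbation draws, completing in well under a
minute on one CPU.  All randomness flows from explicit seeds.  Notable
numerical conventions, collected: banker's rounding for stage boundaries;
strict thresholds for all exceedance indices; nearest-grid midpoint ties to
the lower value; sample (ddof = 1) SD for contribution significance;
linear-interpolation percentiles with strict comparison for extremes;
stable tie-breaks by identifier in rankings; median imputation for
undefined HTC and missing soil values, logged.
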