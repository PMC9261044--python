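# Methods

`actigeo` re-implements, as a tested pipeline on synthetic data, an analysis
design used in urban-health research: wearable accelerometer + GPS streams are
reduced to minutes of physical activity located in small census polygons
(dissemination areas, DAs), joined to built-environment and gentrification
exposures, and modelled with city-stratified multilevel negative-binomial
regressions reported as incidence rate ratios (IRRs). Because studies of this
kind rest on confidential location data, the package ships a synthetic-city
generator with planted parameters; every downstream stage is validated against
that planted truth.

## Sensor processing

**Counts.** Raw tri-axial acceleration (g units, >= 30 Hz) becomes integer
"activity counts" through a frequency-filtering cascade: resample to 30 Hz
(linear interpolation), zero-phase Butterworth band-pass (order 3, 0.25-2.5 Hz
— the human-movement band; zero DC gain removes static gravity), rectify,
dead-band (default 0.05 g, the noise floor), saturate (2.0 g), quantize
(8 bits over the saturation range, i.e. 1 quantum = 15.6 mg), integrate per
second, and sum seconds into clock-aligned epochs (default 60 s, floored to
the device's local wall-clock minute). The cascade is monotone in input
amplitude below saturation, which the tests exploit. The constants are
configuration, not a claim of brand-exact firmware replication; different
devices use different constants but the same architecture.

**Non-wear (Choi).** On vertical-axis counts/min: a minute is non-wear iff it
belongs to an interval of >= 90 min of zeros, tolerating interruptions of
<= 2 consecutive nonzero minutes whose 30-min flanks on both sides are all
zero. Tolerated interruptions count toward interval length; an interruption
at the series edge (no full flank) is genuine wear. Window/tolerance/flank
are configurable (defaults 90/2/30). The implementation is run-length based;
the test suite holds it to *exact* equality with a brute-force
interval-enumeration oracle on 10,000 random day-length series. Missing
minutes are zero-filled before detection, with the gap count reported — the
detector itself refuses NaNs. No valid-day wear-time criterion is applied
anywhere; all worn minutes count.

**Intensity.** Worn minutes are classified by counts/min cut points (defaults
0-99 sedentary, 100-2019 light, 2020-5998 moderate, >= 5999 vigorous — the
Troiano thresholds commonly used for adult hip-worn data). PA = light +
moderate + vigorous; MVPA = moderate + vigorous. Whole-minute granularity is
assumed throughout; sub-minute wear transitions are out of scope.

## GPS fusion and aggregation

1 Hz fixes are reduced to one location per clock minute by the component-wise
median (mean of middle order statistics at even n) — order-statistics
testable, and adequate at sub-minute spatial scales; the geometric median
would differ negligibly here. Minutes with a worn class but no fix are kept
through fusion with an absent location and dropped *with accounting* at
aggregation, so the pipeline reports its data cleaning rather than silently
discarding. Fixes without a worn class are dropped.

Located worn minutes are assigned to DA polygons by containment; points on a
shared boundary go to the lexicographically smallest DA id (a deterministic
tie-break), points outside every polygon are dropped and counted. Aggregation
groups by participant x local calendar date x DA, summing minutes per class;
minutes are never split across dates. `is_home_da` flags the participant's
home DA, weekend = Saturday/Sunday, and daily city-wide precipitation (mm)
and mean temperature (C) are joined by date. The invariant "located worn
minutes = sum of row totals + dropped-record count" holds exactly per
person-day and is enforced at cohort scale in the tests.

## Exposures

* **Active-living composite**: counts of intersections, dwellings, points of
  interest and transit stops within a circular 1-km buffer of each DA
  centroid; each layer z-scored across DAs (a zero-variance layer contributes
  0 with a warning), summed, and cut into quintiles 1-5. The composite is
  invariant to uniform translation of any layer.
* **Proximity**: ten block-level amenity scores on [0,1]
  (employment, pharmacy, childcare, health, grocery, primary/secondary
  education, library, transit, parks); DA value = median over member blocks;
  quintiles pooled over all DAs of all cities.
* **Quintile rule** (used everywhere): average ranks for ties, cut at the
  empirical 20/40/60/80 percentiles of the ranks, left-closed intervals. Ten
  distinct values give exactly two per quintile; an all-tied vector collapses
  to a single bin. Quintiles enter models as numeric 1-5 scores (one unit =
  one quintile, assumed linear).
* **Gentrification** (Ding-style, two census waves): a tract is *eligible*
  when baseline median household income is strictly below the metro median;
  an eligible tract is *gentrified* when (median gross rent OR median home
  value grew more than citywide) AND (college-educated share grew more than
  citywide); otherwise *low SES, not gentrified*; non-eligible tracts are
  *high SES*. Growth is compared as relative change by default; an absolute
  mode is available because the underlying rule's metric is reported
  inconsistently across applications. Tracts with missing wave values are
  flagged unclassifiable. Tract classes and the (externally supplied) urban
  compactness score broadcast to member DAs.

## The model

Per city and outcome (PA or MVPA minutes per person-day-DA row):

    y_ij | b_i ~ NB2(mu_ij, theta),   Var = mu + mu^2/theta
    log mu_ij = x_ij' beta + b0_i + b1_i * t_ij
    (b0_i, b1_i) ~ N(0, Sigma)   (correlated intercept and day slope)

with t the within-person observation-day index, centred. There is no
exposure offset: the outcome is minutes per row and the design models counts
directly. The marginal likelihood integrates the random effects per
participant by adaptive Gauss-Hermite quadrature: per group, a vectorised
Newton ascent finds the conditional mode of the joint density (strictly
concave in b, so warm starts are safe), the integrand is re-centred and
scaled by the Cholesky factor of the negative Hessian there, and a tensor
grid of Hermite nodes (default 7 per dimension; 1 = Laplace approximation)
is summed with `logsumexp`. On a small instance the quadrature agrees with
dense 2-D grid integration to ~1e-13 (the test tolerance is 1e-6).

Estimation maximizes over beta, log theta, log RE standard deviations and an
atanh-correlation with L-BFGS-B (numerical gradients); starting values come
from a Poisson GLM plus a moment estimate of theta. Standard errors are from
the inverted numerical Hessian of the full parameter vector; IRR = exp(beta)
with Wald 95% intervals on the log scale and no multiple-testing correction.
Non-convergence is flagged on the fit object, never silent; a rank-deficient
design raises naming the collinear columns; rows with missing covariates are
dropped complete-case with a logged count. With the RE standard deviations
pinned at the lower bound the fit reproduces a plain NB regression to 1e-4
(statsmodels oracle), and an independent R implementation (glmmTMB, Laplace)
agrees to ~0.01 on fixed effects in the cross-check test.

`run_study` fits 2 outcomes x cities, main plus a sensitivity arm restricted
to rows with >= 5 min dwell (configurable; threshold 0 reproduces the main
fits exactly), and emits IRR tables plus a per-city Spearman correlation
matrix of the exposure measures. A stratum that fails its preconditions is
reported and skipped without aborting the others.

## The synthetic city

**Geometry.** DAs are `cell_size_m` squares (default 500 m) on a rectangular
grid, tiling the extent without overlap; consecutive runs of `das_per_tract`
DAs form tracts. The planar frame maps to WGS84 by a fixed affine anchored
near 45.5 N (exactly invertible, so containment is frame-independent).
Amenity layers are homogeneous Poisson point processes.

**Exposures.** The generator plants DA quintiles (uniform 1-5) and tract
compactness (standard normal) directly — the analogue of the external
databases a real study joins — and *separately* generates raw amenity
layers, block proximity scores and two-wave census panels so the exposure
constructions themselves can be tested against known truth. Census panels
are built so the gentrification classifier reproduces configured class
proportions (citywide growth 10% rent / 15% home value / 20% college share;
gentrified tracts exceed the rent and college growth, the rest fail the
college condition).

**Days.** A wear day (default 480 min starting 09:00, matching the
mid-range of daily wear in studies of this design) is a sequence of dwell
episodes: home, a configurable number of destination DAs (default 2 x
45 min) chosen with probability increasing in the destination's
active-living quintile, then home again. Transitions are snapped to minute
boundaries by default, so every minute lies wholly in one DA; a
constant-speed GPS travel mode exists for realism-oriented runs but is off
by default because pass-through rows (structurally zero counts in briefly
traversed DAs) would make the generating process differ from the fitted
model and contaminate recovery benchmarks. The mobility process is a
deliberate stand-in — observational studies record mobility, they do not
model it — so nothing downstream depends on its realism beyond producing
multi-DA person-days.

**Activity.** For each visited DA with T worn minutes, PA minutes are
`min(T, NB(mu, theta))` with `log mu = beta.x + b0 + b1 * centred day`;
quintile covariates are centred at 3 inside the generator so the planted
intercept (default log 3) is the expected PA per median-DA visit. Defaults:
IRRs 1.3 per active-living quintile, 1.1 per parks quintile, 0.6 per
compactness unit, 30 for the home DA (the order of magnitude such studies
report), 0.95 weekend, ~1.0 weather; theta = 4; RE sds 0.35 (intercept) and
0.03 (slope), correlation 0.2. With these sizes the truncation at T binds on
well under 2% of home rows, a negligible bias acknowledged in the recovery
benchmark. PA splits into light/moderate/vigorous multinomially (0.70 /
0.25 / 0.05); the rest of T is sedentary. Setting `home_dwell_share` instead
rescales the home mean each person-day so the *expected* share of PA minutes
at home equals the planted share exactly (random effects and day-level
factors cancel in the ratio); this mode and the planted home IRR are
mutually exclusive by construction.

**Fidelity levels.** The same day plan can be materialized as (a) analysis
rows directly (cohort scale), (b) minute counts drawn uniformly inside the
planted class band (sedentary minutes get small nonzero counts, so only
planted device-off gaps produce zero runs) plus 1 Hz GPS jitter inside the
minute's DA, or (c) a 50 Hz tri-axial stream whose vertical axis carries a
1.5 Hz tone at a class-calibrated amplitude over 1 g gravity. Amplitudes are
calibrated per cut-point configuration by bisection on the cascade's
amplitude-counts map; the signal round-trip reproduces the intended class on
>= 99% of minutes (band-edge filter leakage accounts for the rest). Plan and
materialization draw from separate seeded streams, so all three levels share
identical row truth — verified exactly in the tests. Full-rate synthesis is
intended for short spans; cohort simulations use counts or table mode.

**What the generator does not emulate:** GPS outages beyond planted
whole-minute dropouts, positional error larger than a few metres, urban
canyon effects, road networks, multi-day battery decline, seasonal behaviour
change, or any behavioural response of people to their environments beyond
the planted log-linear model. Passing tests therefore demonstrate that the
pipeline recovers what it is pointed at under the stated model, not that the
model is true of any real cohort.

## Validation studies and chosen problem sizes

* **Recovery**: 80 replicates of 100 participants x 8 days x ~3 rows/day in
  a 100-DA city, fit with 3-point-per-dimension adaptive quadrature (the
  estimates match 5- and 7-point quadrature to four decimals on this design;
  the smaller grid keeps the replicate study affordable). Checks: mean
  recovered IRR within 10% of planted per coefficient, Wald 95% CI coverage
  in [0.90, 0.99]. Replicates redraw city, cohort, exposures and weather.
* **Home share**: 100 participants x 4 days planted at 0.45, run through the
  full count/GPS/fusion/aggregation path. The Monte-Carlo error of the
  estimate is the ratio-estimator SE over person-day clusters (floored at
  the minute-level binomial SE) — person-day totals are overdispersed and
  clustered, so a purely binomial SE would understate it.
* **Conservation**: 50 participants x 7 days with 3 planted missing-location
  minutes per day; located worn minutes equal aggregated totals plus dropped
  records, exactly, per person-day.
* **Choi equivalence**: 10,000 random 1440-min series against the
  enumeration oracle, exact equality.

## Known limitations

* The count cascade is architecture-faithful, not device-exact; absolute
  count magnitudes are only meaningful relative to the configured cut points
  (the signal generator calibrates itself against the same cascade).
* Numerical Hessians can be non-PD when variance parameters sit at a bound;
  affected terms get NaN standard errors rather than fabricated ones.
* Laplace (1-point) fits are fast but can differ from adaptive quadrature by
  a fraction of a standard error on small counts; quadrature is the default.
* The dwell-episode mobility model produces no within-minute DA straddling
  by default; enabling constant-speed travel re-introduces it and with it
  pass-through rows that the NB model does not describe.
* Tract-level measures broadcast uniformly to member DAs; no small-area
  interpolation is attempted.
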