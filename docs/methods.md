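# Methods

This note documents the models, conventions and default parameters used by
`phenoflux`, the design choices made where several defensible options
existed, and what the synthetic-data tests do and do not demonstrate about
real observations.

## Calendar and growing season

All computations use a fixed 365-day year (DOY 1–365); leap days are
dropped when calendar dates are ingested. Month anchors on this axis:
May 1 = DOY 121, Oct 1 = DOY 274, Nov 1 = DOY 305. The growing season is
the half-open window [May 1, Oct 1), i.e. DOY ∈ [121, 274); the
growing-season mean temperature T_GS is the arithmetic mean of daily means
over that window, reported missing when coverage falls below 80 %.

## The seasonal curve family

Greenness and productivity seasons are modelled as a double logistic

    y(t) = b + a·[ expit(k(t−m)) − expit(r(t−n)) ],   expit(x) = 1/(1+e^(−x))

with background `b`, amplitude `a`, spring rate/inflection `k`, `m` and
autumn rate/inflection `r`, `n`. The curve rises from `b` to a plateau of
≈ `a + b` and returns to `b`. Two notes on provenance conventions:

* Printed forms of this family sometimes sum two rising logistics and
  reuse the symbol "e" for both Euler's number and the autumn rate; such a
  sum is monotone and cannot produce a seasonal peak. The form above —
  rising term minus a second rising term — is the one consistent with
  "background `b`, maximum `a + b`" and is used both in the generator and
  in the fit, so that extraction is exactly invertible at zero noise.
* The autumn rate is a free fourth parameter, fitted independently of the
  spring rate.

The second derivative of a logistic limb `expit(k(t−m))` has its local
maximum at `t = m − ln(2+√3)/k`; the falling limb contributes a second
maximum at `t = n + ln(2+√3)/r`. These closed forms are the oracle for the
curvature-based extractor (`ln(2+√3) ≈ 1.317`; 13.2 days at k = 0.1 d⁻¹).

## Extractors and their definitional targets

Each extractor has a *different* operational definition of the season
start, and therefore a different zero-noise target:

* **Camera greenness**: daily Gcc is composited to its 90th percentile in
  non-overlapping 3-day windows, optionally Savitzky–Golay smoothed; the
  year's baseline/peak are the 10th/90th percentiles of the composited
  curve, and SOS is the first spring day at or above
  `baseline + 0.5·(peak − baseline)`, linearly interpolated between
  bracketing observations and rounded to the nearest day. At the spring
  inflection the logistic is exactly at half amplitude, so the zero-noise
  target is the true inflection day itself (recovered to ≤ 1–2 days; the
  small residual comes from composite window labelling and the percentile
  baseline).
* **NDVI**: Savitzky–Golay smoothing (default window 7, polyorder 2 — the
  source methods name the filter but not its settings), nonlinear
  least-squares double-logistic fit, then SOS/EOS at the first and second
  local maxima of the fitted curve's second derivative on a 0.1-day grid.
  The curvature maximum *leads* the inflection by `ln(2+√3)/k` days by
  construction (≈ 13 days at the default k = 0.1), so at 15-day composite
  cadence the extracted date still lies within one sampling interval of
  the true transition.
* **GPP**: singular-spectrum-analysis smoothing (default window 60 days,
  4 components — again a documented choice, not a stated value), then SOS
  at the first day in the year's first half where smoothed GPP exceeds
  15 % of the multi-year daily maximum and stays above it for 5
  consecutive days. The persistence rule operationalizes "turning point",
  which is otherwise undefined for noisy upcrossings. A 15 %-of-maximum
  threshold is definitionally crossed well before the inflection
  (≈ 21 days at the default curve shape), so the zero-noise target is the
  analytic crossing day of the clean curve, not the inflection. Because
  all three definitions differ from the true transition only by
  *constant* offsets, year-to-year anomalies — the quantity all downstream
  statistics use — are unaffected.

Double-logistic fitting initializes from data percentiles (b₀ = 5th
percentile, a₀ = 95th − 5th, m₀/n₀ = first/last half-amplitude crossings,
k₀ = r₀ = 0.1 d⁻¹), bounds a, k, r > 0 and 1 ≤ m < n ≤ 365, and allows up
to 5 jittered restarts; non-convergent site-years are flagged and excluded
downstream rather than raised.

## Screening rules

* MAD fence: keep `v` iff `|v − median| ≤ k·MAD` with unscaled
  `MAD = median(|v − median|)` and default k = 2.5. No 1.4826 normality
  constant is applied, because the rule is stated as a multiple of the raw
  MAD. When MAD = 0 only values equal to the median survive. Values
  exactly on the fence are retained ("exceeding" is strict).
* Bare-land mask: a site/pixel is retained iff the mean of its annual mean
  NDVI is ≥ 0.1 (boundary inclusive, since the exclusion rule "< 0.1" is
  strict).
* Record length: a site(-source) series must have at least `min_years`
  years with a valid SOS; when a daily-records threshold is given, years
  with ≤ that many daily observations are dropped first
  (strictly-greater rule).

## Climate predictors

* Anomalies are z-scores per site: `(v − mean)/SD` with the sample SD,
  requiring ≥ 3 non-missing years and positive spread. z-scoring (rather
  than mean-centering alone) is what makes the days/°C back-transform
  `slope_norm × SD(SOS)/SD(T)` exact: on z-scored data the OLS slope
  equals the Pearson correlation, and the back-transform reproduces the
  raw-scale OLS slope.
* Chilling days count daily means in the closed interval [0, 5] °C;
  forcing accumulates `max(T − 5, 0)` so a day exactly at 5 °C contributes
  nothing. Both accumulate over the half-open window from Nov 1 of the
  previous year to the site's long-term mean SOS (rounded to the nearest
  day), computed once per site over retained years. Windows with < 90 %
  daily coverage yield missing values; sums are never rescaled.
* Gridded climate is interpolated to sites bilinearly
  (scipy `RegularGridInterpolator`, linear method, no extrapolation
  outside the grid hull).

## Sensitivity statistics

S_T is estimated per site by OLS of normalized SOS anomalies (year *y*) on
normalized T_GS anomalies (year *y* − 1), with the two-sided t-test
p-value; the pooled estimate across sites is the mean slope with a t-based
95 % CI, significant when the CI excludes zero. Pairs with any missing
member are dropped listwise per site. Site-level slope estimates in
days/°C are heavy-tailed when the predictor variance is small (the
back-transform divides by SD(T)), which inflates the across-site spread;
the pooled mean remains unbiased and its CI attains nominal coverage (both
verified by simulation in the test suite).

Partial correlation removes linear covariate effects by correlating the
residuals of x and y regressed on the controls (equivalently via the
inverse correlation matrix — both routes are implemented and agree to
1e−10), with a t-approximate p-value on `df = n − 2 − #controls`.
Group comparisons use one-way ANOVA followed by Tukey's HSD (studentized
range); the compact letter display uses the insert-and-absorb algorithm
over the significance matrix, with ties broken by group order.

## Attribution

The structural model is the directed acyclic graph in which each climate
driver (temperature, radiation, precipitation, soil water content, CO₂)
points at both GPPmax and SOS, and GPPmax points at SOS. Estimation is
piecewise (local): one OLS per endogenous node on its parents, fitted on
z-scored variables so coefficients are standardized paths. Overall
consistency is judged by the test of directed separation: for every
non-adjacent pair (excluding pairs of two exogenous drivers, whose free
covariance the directed model does not constrain), the later node in
topological order is regressed on the earlier one plus the union of both
nodes' parents, and the earlier node's coefficient p-value enters
Fisher's `C = −2Σ ln pᵢ`, which is χ²(2k) under the model. The default
graph is saturated, so its basis set is empty and C = 0 on 0 df — this is
reported and flagged rather than hidden, and the calibration of the test
is exercised on pruned graphs. Indirect effects are path products
(`climate→GPPmax × GPPmax→SOS`); totals are direct + indirect and match
marginal regression slopes by path tracing.

Random-forest importance uses a regression forest (default ntree = 1000,
mtry = 4 — stated method settings) with permutation importance computed on
each tree's out-of-bag samples: the mean increase in OOB MSE when a
predictor is permuted. Permutation (not impurity) importance is used
because impurity importance is biased by predictor scale and cardinality.
Percentage shares are taken on the *magnitude* of the mean increases:
under a pure-noise response the per-predictor increases fluctuate around
zero, and normalizing clipped values would turn sign noise into spuriously
concentrated shares, whereas magnitudes give near-uniform shares under the
null and still assign essentially all weight to a genuinely dominant
predictor.

## The synthetic generator

The generator emulates the statistical structure of multi-site phenology
networks, not their instruments:

* Daily temperature: `mean + amplitude·cos(2π(doy−200)/365) +
  trend·(years/10) + N(0, σ²)`, defaults 8 °C mean, 10 °C amplitude,
  σ = 4 °C (a realistic daily-anomaly spread for mid-latitude sites; it
  implies an interannual T_GS standard deviation of about 0.3 °C through
  the 153-day average).
* Phenology truth: `SOS(y) = base + S_T·(T_GS(y−1) − mean T_GS) + N(0,
  σ_SOS²)` with defaults base = 120, S_T = −2 days/°C, σ_SOS = 3 days,
  season length 160 days; noise is truncated to keep 1 ≤ SOS < EOS ≤ 366.
  The first year carries no previous-season effect and is flagged.
* Seasonal curves sample the double logistic with the spring inflection at
  the true SOS and autumn inflection at the true EOS. Observation-noise
  defaults (NDVI σ = 0.02 at 15-day cadence, Gcc σ = 0.005 daily, GPP
  σ = 0.5 gC m⁻² d⁻¹ on amplitude 10) are fixture choices — no source
  states instrument noise levels.
* The flux panel draws climate drivers as independent standard normals and
  builds GPPmax and SOS as linear combinations whose noise variances are
  calibrated so every variable has unit variance; the generating
  coefficients are then *exactly* the standardized path coefficients,
  which is what makes path-recovery tests sharp.

What passing tests therefore show: the estimators invert their own
definitions, recover planted effects at realistic noise levels, and are
correctly calibrated under the null. What they do not show: robustness to
features of real data that the generator deliberately omits — cloud and
snow contamination, sensor drift, camera exposure changes, correlated
climate drivers, spatial autocorrelation between sites, and asymmetric or
double-peaked seasons.

## Pipeline conventions

The orchestrated run derives all stage randomness from a single root seed
via deterministic substreams, so re-running a configuration reproduces
byte-identical CSV outputs (verified by manifest checksums). Records
dropped between stages are exactly those in the filter reports. The demo
configuration uses 20 sites × 15 years for the extraction network and
25 flux sites × 20 years for the attribution panel — small enough to run
in seconds while leaving the planted effects comfortably detectable in the
pooled statistics. In the demo summary the pooled S_T is assessed across
all site-source slope estimates, which triples the effective sample at
this deliberately small scale.

## Known limitations

* Per-site OLS assumes independent years; no allowance for autocorrelated
  phenology series or mixed-effects pooling across sites (sites are fitted
  separately by design).
* The d-separation test treats its component p-values as independent;
  calibration was verified by simulation for the graphs used here but is
  asymptotic in general.
* The 365-day calendar introduces ≤ 1-day distortions for real dated data
  around leap years.
* Bare-land masking and record screening operate on provided series; no
  ecoregion/biome map masking is implemented.
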