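# phenoflux

Tools for linking **current-year spring phenology** to **previous-growing-season
climate and carbon uptake** in temperate and boreal forests, built for
ecologists who work with multi-site time series of vegetation greenness and
eddy-covariance productivity.

Warm conditions during the previous May–September are associated with earlier
leaf-out the following spring, and one candidate mechanism is carbon storage:
a productive previous season (high photosynthetic uptake, GPP) leaves more
reserves for spring reactivation. Testing that chain requires several pieces
of machinery that this package provides as a tested, reusable pipeline:

1. **Phenology extraction** from three curve families:
   * camera greenness — green chromatic coordinate
     `Gcc = G_DN / (R_DN + G_DN + B_DN)`, composited to its 90th percentile,
     with the season start (SOS) at the half-amplitude spring crossing;
   * satellite NDVI — Savitzky–Golay smoothing, a double-logistic fit
     `y(t) = b + a·[1/(1+e^{−k(t−m)}) − 1/(1+e^{−r(t−n)})]`,
     and SOS/EOS at the first/second local maximum of the fitted curve's
     second derivative (for a logistic limb this sits exactly
     `ln(2+√3)/k` days before the inflection);
   * flux-tower GPP — singular-spectrum-analysis smoothing, SOS at a
     sustained crossing of 15 % of the multi-year daily maximum, plus the
     carbon metrics GPPmax (annual maximum) and mean May–September GPP.
2. **Record screening**: a 2.5 × MAD outlier fence, a bare-land mask
   (mean annual NDVI < 0.1), and minimum-record-length filters.
3. **Climate predictors**: growing-season (May–September) means, z-scored
   anomalies, chilling days (daily mean in [0, 5] °C) and forcing
   degree-days (> 5 °C) accumulated from November 1 to the mean SOS, and
   bilinear interpolation of gridded climate to site coordinates.
4. **Sensitivity statistics**: per-site temperature sensitivity
   `S_T` — the OLS slope of normalized SOS anomalies on normalized
   previous-season temperature anomalies, back-transformed to days/°C by
   `slope × SD(SOS)/SD(T)` (negative = warming advances spring) — with
   pooled t-based confidence intervals, partial correlations controlling
   covariates, and ANOVA + Tukey HSD with compact letter displays.
5. **Attribution models**: a piecewise structural equation model of the
   climate → GPPmax → SOS graph (component OLS regressions, standardized
   paths, Fisher's `C = −2Σln pᵢ ~ χ²(2k)` test of directed separation)
   and random-forest variable importance (ntree = 1000, mtry = 4,
   out-of-bag permutation importance).
6. **A synthetic multi-site generator** with fully recorded ground truth
   (true SOS/EOS, the planted days/°C effect, the generating path
   coefficients), so every stage is testable end to end without any
   download.

## Worked example

`examples/02_temperature_sensitivity.py` builds a 60-site, 30-year network
with a planted sensitivity of −2 days/°C and recovers it:

```
pooled S_T: -2.63 days/degC, 95% CI [-3.54, -1.73] (planted -2.0; significant: True)
ANOVA F = 0.99, p = 0.379
Tukey letters (same letter = indistinguishable): {'Fagus': 'a', 'Quercus': 'a', 'Tilia': 'a'}
```

The pooled confidence interval covers the planted −2 days/°C and excludes
zero (site-level slope estimates are heavy-tailed, so individual sites are
noisy; the network mean is what carries the signal), and species generated
with identical sensitivity correctly share one Tukey letter.

`examples/03_attribution_sem_rf.py` fits the structural model on a
500-site-year panel drawn from known standardized coefficients:

```
standardized paths (truth in parentheses):
    temperature -> gppmax: +0.599 (+0.60)  p=5e-60
         gppmax -> sos:    -0.498 (-0.50)  p=4.8e-17
    temperature -> sos:    +0.120 (+0.15)  p=0.024
...
random-forest importance shares (%):
gppmax           88.2
temperature       5.8
```

Every standardized path lands within sampling error of its generating
value, the indirect temperature effect through GPPmax (−0.30) opposes the
direct one (+0.12), and the forest ranks GPPmax as the dominant predictor.

The other examples show single-site phenology extraction
(`01_extract_phenology.py`) and the full orchestrated pipeline with CSV
outputs and a manifest (`04_full_pipeline.py`). A thin CLI wraps the
pipeline for shell use:

```bash
phenoflux write-config --out run.yaml --seed 0
phenoflux run-all --config run.yaml --out results/
phenoflux summarize --config run.yaml
```

## Layout

```
src/phenoflux/
  series.py      # DailySeries container, 365-day calendar
  curves.py      # double-logistic family and closed-form curvature offsets
  synthetic.py   # multi-site generator with recorded ground truth
  qc.py          # MAD fence, bare-land mask, record-length filters
  extraction.py  # Gcc / NDVI / GPP phenology and carbon metrics
  climate.py     # season means, anomalies, chilling/forcing, interpolation
  stats.py       # S_T regression, slope CIs, partial corr, ANOVA + Tukey
  attribution.py # piecewise SEM + RF importance
  pipeline.py    # stage orchestration, RunConfig, manifest
  cli.py         # thin click wrapper (run-all / summarize / write-config)
```

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
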