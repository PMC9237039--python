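"""Extract start-of-season dates from three kinds of seasonal curves.

Builds one synthetic site with a known spring transition (DOY 120), then
runs the three extractors: the half-amplitude crossing on composited
camera greenness, the curvature maxima of a double-logistic NDVI fit, and
the sustained 15%-of-maximum threshold on SSA-smoothed GPP.  The printed
dates differ between methods by design: the curvature method leads the
inflection by ln(2+sqrt(3))/k days, and the 15% threshold is crossed well
before the inflection — what matters downstream is year-to-year variation,
which all three track.
"""
import numpy as np

from phenoflux import extraction, synthetic
from phenoflux.series import concat_series

site = synthetic.SiteConfig("DEMO", 48.0, 8.0, 4, 2000, "Fagus")
temp = synthetic.generate_temperature(site, noise_sd=0.0, seed=1)
truth = synthetic.generate_phenology_truth(site, temp, base_sos=120.0,
                                           true_st=0.0, sos_noise_sd=0.0,
                                           seed=1)
print(f"true SOS for every year: {truth[0].true_sos:.0f} "
      f"(EOS {truth[0].true_eos:.0f})")

gcc = concat_series([synthetic.generate_seasonal_curve(t, "gcc", seed=i)
                      for i, t in enumerate(truth)])
smoothed = extraction.savitzky_golay(extraction.gcc_composite_90(gcc))
print("camera greenness (half-amplitude):",
      [extraction.gcc_sos(smoothed, t.year) for t in truth])

ndvi = [synthetic.generate_seasonal_curve(t, "ndvi", seed=10 + i)
        for i, t in enumerate(truth)]
sos_eos = []
for t, c in zip(truth, ndvi):
    params, diag = extraction.fit_double_logistic(c, t.year)
    sos_eos.append(extraction.extract_sos_eos_from_fit(params))
print("NDVI (curvature maxima, SOS/EOS):", sos_eos)

gpp = concat_series([synthetic.generate_seasonal_curve(t, "gpp", seed=20 + i)
                      for i, t in enumerate(truth)])
sm = extraction.ssa_smooth(gpp)
mym = float(np.max(sm.value))
print("GPP (15% threshold):",
      [extraction.gpp_sos(sm, t.year, mym) for t in truth])
print("carbon metrics year 2000:",
      extraction.carbon_metrics(sm, 2000))
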