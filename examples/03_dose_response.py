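"""Population dose-response to direct PPARgamma activation with Hill fits.

A 12-point two-fold dilution series of the rosiglitazone channel (plus a
vehicle control) is applied to ensembles for 48 h; the population-mean
transcription-factor levels give smooth sigmoids whose steepness reflects
the distribution of single-cell switching thresholds.
"""

from adiposwitch import (conversion_span, ensemble_dose_response_48h,
                         reference_params)

params = reference_params()
curve, fits = ensemble_dose_response_48h(params, n_cells=400, seed=2)

print("dose     frac_high  mean C/EBPb  mean PPARg  mean C/EBPa")
for _, r in curve.iterrows():
    print(f"{r.dose:7.4f}  {r.frac_high:9.3f}  {r.cebpb:11.2f}  "
          f"{r.pparg:10.2f}  {r.cebpa:11.2f}")

print()
for name, f in fits.items():
    print(f"{name:6s}: Hill n = {f.hill_n:.2f}, EC50 = {f.ec50:.3f}")
print(f"conversion span (5% -> 95% of cells): {conversion_span(curve):.0f}-fold")
print()
print("Single cells switch all-or-none; the smooth Hill ~2.5 sigmoids arise")
print("from averaging cells whose thresholds vary, and the converted")
print("fraction climbs from none to all over a ~16-fold dose range.")
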