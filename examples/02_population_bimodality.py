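"""Cell-to-cell variability turns a uniform stimulus into two subpopulations.

Runs a 500-cell ensemble (lognormal parameter noise: 15% CV for the
PPARgamma group, 30% for C/EBPbeta and C/EBPalpha) through 48 h of
induction plus 48 h washout, then classifies the end-state PPARgamma
distribution.
"""

from adiposwitch import (NoiseSpec, classify_bimodality, reference_params,
                         run_population, standard_dim_protocol)

params = reference_params()
table = run_population(500, standard_dim_protocol(48.0, 96.0), params,
                       NoiseSpec(), sample_times=[96.0], seed=1)

res = classify_bimodality(table["pparg"].to_numpy())
print(f"bimodal: {res.is_bimodal}")
print(f"low / high fractions: {res.frac_low:.2f} / {res.frac_high:.2f}")
print(f"low-high threshold: {res.threshold:.2f} a.u.")
print()
print("Although every cell receives the same stimulus, extrinsic parameter")
print("noise splits the population: cells above the switching threshold")
print("commit to the high-PPARgamma adipocyte state, the rest revert.")
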