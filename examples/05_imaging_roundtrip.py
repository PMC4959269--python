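"""Synthetic immunofluorescence round-trip: simulate, render, quantify.

Simulates a small population, renders a multi-channel field (Hoechst nuclei,
nuclear TF stains, cytosolic BODIPY/pAKT), runs the segmentation pipeline
and compares measured with true per-cell intensities.
"""

import numpy as np
from scipy.spatial import cKDTree

from adiposwitch import (ModelState, NoiseSpec, reference_params,
                         run_population, standard_dim_protocol)
from adiposwitch.imaging import (SyntheticFieldSpec, generate_field,
                                 quantify_field)

params = reference_params()
table = run_population(80, standard_dim_protocol(48.0, 96.0), params,
                       NoiseSpec(), sample_times=[96.0], seed=3)
states = [ModelState.from_array(row) for row in
          table[["cebpb", "pparg", "cebpa", "pakt", "ir", "fat"]].to_numpy()]

spec = SyntheticFieldSpec(n_cells=80, seed=3, background_gradient=(0.1, 0.05))
channels, truth = generate_field(spec, states)
measured = quantify_field(channels)

tree = cKDTree(truth[["y", "x"]].to_numpy())
d, idx = tree.query(measured[["y", "x"]].to_numpy())
match = d < 3.0
print(f"cells rendered: {len(truth)}, detected: {len(measured)}, "
      f"matched at 3 px: {match.sum()}")
for ch in ("pparg", "cebpb", "bodipy", "pakt"):
    r = np.corrcoef(truth.loc[idx[match], f'true_{ch}'],
                    measured.loc[match, ch])[0, 1]
    print(f"  {ch:7s} measured-vs-true Pearson r = {r:.3f}")
print()
print("The segmentation (centroids -> 30%-of-peak nucleus masks -> 7 um")
print("dilated cell masks -> annulus background subtraction) recovers the")
print("per-cell expression levels that generated the image.")
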