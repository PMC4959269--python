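"""Hysteresis: the steady state depends on stimulus history.

Sweeps the rosiglitazone channel up from the basal state and back down from
the committed state; in the bistable window the two branches disagree.
"""

import numpy as np

from adiposwitch import reference_params, stimulus_sweep_hysteresis

params = reference_params()
hb = stimulus_sweep_hysteresis(params, relax_h=400.0)

print("dose      PPARg (up-sweep)  PPARg (down-sweep)")
for lv, f, b in zip(hb.levels, hb.forward, hb.backward):
    mark = "  <- bistable" if abs(b - f) / max(f, 1e-9) > 0.10 else ""
    print(f"{lv:8.4f}  {f:16.2f}  {b:18.2f}{mark}")
print()
print(f"bistable window: {hb.window}")
print("Once switched on, the circuit stays on even at zero stimulus -- the")
print("biochemical memory that makes differentiation irreversible.")
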