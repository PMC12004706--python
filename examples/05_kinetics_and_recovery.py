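"""Block-equilibration kinetics and recovery from inactivation.

Left: the onset of inhibition during a sparse pulse train is a single
exponential whose time constant shortens with concentration and with
depolarized holding potentials (tau ~ 1 / (k_on * (C + apparent IC50))).
Right: the drug barely affects recovery after a brief (20 ms) prepulse
but slows recovery after a 5 s prepulse, the signature of
inactivated-state trapping.
"""

import pandas as pd

from navblock import build_protocol, run_protocol
from navblock.analysis import analyze_block_kinetics, analyze_recovery
from navblock.model import default_cell, default_drug, default_gating

cell, gating, drug = default_cell(), default_gating(), default_drug()

# --- equilibration kinetics at two holding potentials -----------------
frames = []
for hp in (-100, -90):
    for conc in (0.0, 4.0, 15.0, 30.0):
        rec, _ = run_protocol(cell, gating, drug,
                              build_protocol("kinetics", holding_potential=hp), conc)
        rec["cell_id"] = f"k{hp}_{conc:g}"
        frames.append(rec)
kin = analyze_block_kinetics(pd.concat(frames, ignore_index=True))
print("tau_observed (s) by concentration and holding potential:")
print(kin.summary.pivot(index="conc_uM", columns="holding_mV", values="tau_s").round(1))

# --- recovery from inactivation ---------------------------------------
frames = []
for pp in (20.0, 5000.0):
    for conc in (0.0, 30.0):
        rec, _ = run_protocol(cell, gating, drug,
                              build_protocol("recovery", prepulse_duration_ms=pp),
                              conc, init="full")
        rec["cell_id"] = f"r{pp:g}_{conc:g}"
        frames.append(rec)
recov = analyze_recovery(pd.concat(frames, ignore_index=True))
cols = ["conc_uM", "prepulse_ms", "percent_fast", "tau_fast_s", "tau_slow_s", "t_half_s"]
print("\nbi-exponential recovery fits:")
print(recov.summary[cols].round(4).to_string(index=False))
# After 20 ms the half-recovery times are indistinguishable; after 5000 ms
# the 30 uM arm recovers markedly slower than vehicle.
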