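"""Fit the nicking-relaxation model to synthetic intensity traces.

Emulates the high-speed imaging experiment: 32 traces at 20 ms frames with
5% noise, each showing a delayed exponential intensity step when the DNA
nicks. The ensemble-mean rate, divided by the dye concentration, gives a
bimolecular on-rate.
"""

import numpy as np

from topobind import RelaxationFit, fit_relaxation, on_rate_from_relaxation, simulate_trace

truth = RelaxationFit(I_initial=60.0, I_final=100.0, k=1.92, t0=2.0)
step = abs(truth.I_final - truth.I_initial)

ks = []
for seed in range(32):
    trace = simulate_trace(truth, frame_interval=0.02, duration=10.0,
                           noise_sd=0.05 * step, seed=seed)
    ks.append(fit_relaxation(trace).k)
ks = np.asarray(ks)
sem = ks.std(ddof=1) / np.sqrt(len(ks))

print(f"true rate          : {truth.k:.3f} 1/s")
print(f"fitted (mean+/-sem): {ks.mean():.3f} +/- {sem:.3f} 1/s  (n = {len(ks)})")
k_on = on_rate_from_relaxation(ks.mean(), 250e-9)
print(f"implied on-rate at 250 nM dye: {k_on:.3g} 1/(M s)")
print("\nAn on-rate of ~8e6 1/(M s) means dye binding, not torsional")
print("relaxation, limits the fluorescence change after nicking.")
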