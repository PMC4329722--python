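"""Spectral response of the network across driving frequencies.

For each driving frequency the driven and undriven conditions are run
with matched noise and compared as 10 log10(PSD_driven / PSD_stat).
The map is dominated by a 1:1 ridge at the driving frequency; the alpha
band gains power only when the driving is slow (below ~2 Hz).
"""

import numpy as np

import neuromass as nm

spec = nm.ExperimentSpec(
    scenario="response_map_frequency",
    duration=160.0,
    seeds=(1,),
    sweep=(0.25, 1.0, 5.0, 10.0),
)
rm = nm.run_response_map(spec)
f = rm.frequencies

print("drive f    ridge (dB)   alpha 8-12 Hz, drive notched (dB)")
for i, fd in enumerate(rm.sweep_values):
    ridge = np.nanmean(rm.db[i][(f >= fd - 0.1) & (f <= fd + 0.1)])
    m = (f >= 8) & (f <= 12)
    for c in (fd, 2 * fd):
        m &= ~((f > c - 0.5) & (f < c + 0.5))
    alpha = np.nanmean(rm.db[i][m])
    print(f"{fd:7.2f}    {ridge:8.1f}    {alpha:8.2f}")

print(
    "\nEvery injected frequency reappears 1:1 in the output (the ridge);\n"
    "the extra alpha-band gain is present for slow driving and vanishes\n"
    "as the driving frequency grows."
)
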