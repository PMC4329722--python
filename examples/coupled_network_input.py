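"""Self-consistent operating point of the coupled four-column network.

Four identical columns coupled all-to-all (K = 15) each receive a
constant 75 Hz plus the firing of the other columns.  The coupling
contributes ~15 Hz on average, placing the effective input near the
89.83 Hz Hopf point — the operating condition for realistic spectra.
Averaging the four EEG signals also attenuates individual spikes.
"""

import neuromass as nm

net = nm.NetworkConfig.homogeneous(4, 15.0, 75.0)
runs = []
for seed in (1, 2, 3):
    ts = nm.simulate(net, sim=nm.SimulationConfig(h=0.001, duration=210.0, seed=seed))
    runs.append(nm.discard_transient(ts, 10.0))

stats = nm.mean_effective_input(runs)
print(f"constant input:              75.0 Hz")
print(f"mean coupling contribution: {stats.coupling_mean_hz:6.1f} Hz")
print(f"mean total pyramidal input: {stats.mean_total_hz:6.1f} Hz")
print(f"coupling coefficient of variation: {stats.coupling_cv:.2f}")

ts = runs[0]
print(f"\nlargest single-column swing: {(ts.eeg.max(0) - ts.eeg.min(0)).max():.1f} mV")
print(f"swing of the 4-column average: {ts.average.max() - ts.average.min():.1f} mV")
print(
    "\nThe total input sits near the Hopf point at 89.83 Hz; the coupling\n"
    "input fluctuates about as strongly as its mean (CV ~ 1), and column\n"
    "averaging suppresses the spiky excursions of individual columns."
)
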