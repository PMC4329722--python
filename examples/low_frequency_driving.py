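"""Cross-frequency power transfer under slow periodic driving.

The coupled network is driven with a 0.25 Hz sine (amplitude 45 Hz) and
with a power-matched multi-sine spanning 0.05-4 Hz.  Slow driving pushes
the network periodically deeper into its oscillatory regime, raising
alpha-band (8-12 Hz) power even though the drive itself contains no such
frequencies; the multi-sine additionally raises low-frequency power.
"""

import numpy as np

import neuromass as nm

amp = nm.calibrate_composed_amplitude(45.0, 0.05, 4.0, 0.05)
print(f"composed-drive amplitude matching a 45 Hz sine: {amp:.2f} Hz")

spec = nm.ExperimentSpec(
    scenario="sine_driven", duration=310.0, seeds=(1,), n_phase_realizations=10
)
res = nm.run_driven(spec)

alpha_stat = nm.band_power(res.psd_stationary, 8.0, 12.0)
alpha_sine = nm.band_power(res.psd_sine, 8.0, 12.0)
low_stat = nm.band_power(res.psd_stationary, 0.05, 4.0)
low_comp = nm.band_power(res.psd_composed, 0.05, 4.0)

print(f"alpha power, stationary:      {alpha_stat:.3f} mV^2")
print(f"alpha power, 0.25 Hz sine:    {alpha_sine:.3f} mV^2  "
      f"({10 * np.log10(alpha_sine / alpha_stat):+.1f} dB)")
print(f"0.05-4 Hz power, stationary:  {low_stat:.3f} mV^2")
print(f"0.05-4 Hz power, composed:    {low_comp:.3f} mV^2  "
      f"({10 * np.log10(low_comp / low_stat):+.1f} dB)")
print(
    "\nBoth drives transfer power into the alpha band; the composed drive\n"
    "also raises low-frequency power, as in scalp recordings under slow\n"
    "vestibular stimulation."
)
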