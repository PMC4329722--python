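# Methods

This note records the model conventions, numerical choices and open
design decisions behind `neuromass`, and states what the test suite does
and does not establish.

## Model and state convention

Each cortical column carries six state variables: the mean postsynaptic
potentials `y0, y1, y2` (mV) and their time derivatives `z0, z1, z2`
(mV/s) — the first-order form of the three second-order synaptic
equations. `y0` is the pyramidal output potential feeding both
interneuron populations; `y1` and `y2` are the excitatory and inhibitory
potentials entering the pyramidal population; the EEG-like observable is
`y1 − y2`, averaged over columns for an electrode-like signal.

The canonical Jansen–Rit constants are the package defaults (see
`ColumnParameters`). They are validated indirectly: with them the
package reproduces the known bifurcation skeleton of the single column
(Hopf points at 89.83 and 315.70 Hz of constant input, spiky-cycle
window ≈ 113.6–137.3 Hz) without any tuning.

The total pyramidal input `p(t)` sums a constant component, the
normalised coupling input, the common deterministic drive and the
per-column OU noise. It may transiently become negative under noise;
no rectification is applied, since the `y1` equation is linear in its
input and nothing in the model constrains the external input's sign.

## Ornstein–Uhlenbeck noise convention

The noise obeys `dξ/dt = −ξ/τ + (√(2D)/τ) ξ_w(t)` with unit-intensity
Gaussian white noise `ξ_w`. Under this convention the stationary
standard deviation is `√(D/τ)` — 48.3 Hz at the reference D = 350 Hz,
τ = 0.15 s — and the autocorrelation decays as `exp(−|lag|/τ)`. The
alternative reading `√(2D/τ) ξ_w` would give a stationary SD of
`√D ≈ 18.7 Hz`, inconsistent with the ≈ 48 Hz dispersion the reference
parameterisation is meant to produce, and is therefore rejected. The
48 Hz figure is a standard deviation (its units are Hz); `D` is stored
under its conventional label "Hz" without resolving its formal dimension.

Each column receives an independent OU stream from a seed-derived
substream (`SeedSequence(seed).spawn(N)`, in column order), so `(seed, N)`
fully determine the noise. The initial noise value is drawn from the
stationary distribution to avoid an extra transient. A test-only
`share_noise` mode feeds all columns one stream to exercise the
column-symmetry invariant.

## Driving signals

The sine drive is `Ã sin(2πft)` (reference Ã = 45 Hz, f = 0.25 Hz). The
composed drive is a sum of sines on the grid `f_min : f_step : f_max`
(reference 0.05–4 Hz in 0.05 Hz steps, 80 components) with weights
`10^(−(f_n − f_min)/(f_max − f_min))` — a tenfold amplitude decay across
the grid — and per-component random phases uniform in [0, 1) cycles.
Component indices are obtained by nearest-integer rounding of
`f_min/f_step` and `f_max/f_step` with relative tolerance 1e-6; the
degenerate single-component grid gets weight one.

Power matching equates the phase-averaged mean power
`Ã′² Σ w_n² / 2` to the sine's `Ã²/2`, giving
`Ã′ = Ã / √(Σ w_n²)` = 10.76 Hz for the reference settings. A
brute-force time-average over 20 periods of the slowest component
confirms the match within 5%.

## Integration

The stochastic Heun scheme advances columns and OU noise synchronously:
an Euler predictor, a trapezoidal corrector, and one shared white-noise
increment per step applied in both stages, so the scheme reduces to
deterministic Heun when D = 0 (global error O(h²), verified against an
8th-order adaptive reference). The drive is evaluated at `t` in the
predictor and `t + h` in the corrector. The reference step is h = 1 ms;
halving it moves ensemble alpha-band power by well under 5%.

Initial conditions default to the all-zero state (the reference
protocol's 10 s discarded transient absorbs the settling); note that in
the bistable input range 89.83–113.58 Hz the all-zero state lies in the
basin of the *lower stable fixed point*, so deterministic runs from rest
do not show alpha oscillations there — the alpha cycle must be reached
from the neighbourhood of the upper (unstable-focus) equilibrium.

The inner loop is compiled with numba when available; a pure-Python
execution of the same source is the fallback. A Python-level
`heun_step` mirrors the kernel (agreement ≲ 1e-10 over 100 stochastic
steps) and serves as its readable specification.

## Bifurcation analysis

Equilibria come from the scalar reduction in `y = y1 − y2`, solved by
dense bracketing (2001 points on [−50, 50] mV) plus Brent refinement,
then lifted to the full six-dimensional state. In the bistable range the
column has three equilibria (stable node, saddle, unstable focus); the
upper branch persists over the whole input range examined. Stability
uses the analytic Jacobian (`Sigm'(y) = r Sigm (1 − Sigm/(2e0))`),
checked entrywise against central finite differences.

Hopf points are located by bisection (to 0.01 Hz) on the sign of the
leading *complex-pair* real part, maximised over branches; purely real
eigenvalues are excluded so the saddle's positive real eigenvalue cannot
mask the crossing. The imaginary part at the crossing gives the nascent
cycle frequency (10.4 Hz at the first Hopf point — squarely alpha).

The spiky-cycle window is found by simulation: at each candidate input a
library of initial conditions (each equilibrium, ±2 and ±10 mV kicks of
`y1` off each equilibrium, the rest state, plus a continuation state
carried over from the last spiky orbit found) is integrated
deterministically for 50 s in one batched call; trajectories are
classified after a 10 s settle, and the existence boundary of the spiky
label is bisected to 0.1 Hz. Continuation is what tracks the attractor
reliably near its upper fold; with 50 s runs the measured offset
(137.30 Hz) sits ~0.1 Hz below the literature value (137.38 Hz), an
expected finite-run bias that is well inside the ±0.5 Hz acceptance
band.

Classification thresholds: peak-to-peak < 0.1 mV → fixed point;
dominant frequency < 6 Hz *and* peak-to-peak > 8 mV → spiky cycle;
otherwise alpha cycle. The thresholds sit between the simulated regimes
(alpha: ~10 Hz, ≲ 4 mV; spiky: ~3–5 Hz, > 10 mV) and are overridable.
The dominant frequency is the periodogram peak above 0.5 Hz.

## Spectral analysis

Welch PSDs use Hann-windowed 20 s segments with 10 s overlap (0.05 Hz
resolution — exactly the composed drive's grid) and per-segment mean
removal; without detrending the 0 Hz bin dominates every low-frequency
comparison. One-sided density normalisation makes the integral of the
density equal the signal variance (verified on pure tones to 2% and on
white noise to 10%); all headline comparisons are ratios, which are
normalisation-invariant. On a simulated OU path the estimate matches the
closed-form Lorentzian `2·(2D/τ²)/((1/τ)² + (2πf)²)` within 15% over
0.1–100 Hz.

The embedded alpha peak of the broadband spectra is quantified as the
smoothed in-band (7–13 Hz) maximum of the density over a log-log linear
interpolation between the flanking bands (5–7 and 13–16 Hz), in dB. A
raw local maximum would miss it: the peak rides on a steep 1/f^b decay.
Response maps compare driven and undriven runs with matched noise seeds
(`10 log10` density ratio), which reduces the variance of the dB maps
without biasing their expectation; band statistics around a drive line
notch ±0.5 Hz around the line and its first harmonic (module-level
helpers for the 0–5 Hz comparison use a ±0.1 Hz notch, two Welch bins,
for the 0.25 Hz line).

## Experiment defaults and scaled-down protocol

Reference conditions: N = 4 columns all-to-all with K = 15 and
p_const = 75 Hz (single column: 90 Hz), D = 350 Hz, τ = 0.15 s, 1010 s
runs with the first 10 s discarded. The choice K = 15 / 75 Hz is
self-consistent: the coupling contributes ≈ 14–15 Hz on average, placing
the mean total input at ≈ 90 Hz with a coupling coefficient of variation
near one. Sweep grids for the response maps default to
Ã ∈ {0, 15, 30, 45, 60, 90} Hz, f ∈ {0.1 … 25} Hz and N ∈ {2, 4, 8, 16};
the composed-drive ensemble uses 10 phase realisations.

Tests and examples run 100–310 s spans instead of 1010 s: all asserted
effects (alpha peak, band-power changes, response-map structure) are
stable at that scale across seeds; the longer protocol only narrows
stochastic error bars.

## What the tests establish — and what they do not

The suite verifies the deterministic skeleton against independent
oracles (brute-force root scans, finite-difference Jacobians, an
8th-order reference integrator), the noise and drive statistics against
closed forms, and the driven-spectra effects as seeded, scaled-down
stochastic checks. It does not establish quantitative agreement with
any experimental EEG spectrum (no experimental data ships with the
package), coupling-delay robustness, or behaviour under heterogeneous
per-column parameters (unsupported by design: all columns are
identical).

## Known limitations

- Limit cycles are characterised by simulation and classification, not
  by numerical continuation/Floquet analysis; boundaries carry a small
  finite-run bias (see above).
- The classifier assumes transient-free deterministic input; applying it
  to noisy trajectories is meaningless.
- The spiky/alpha thresholds are heuristic constants chosen between two
  well-separated regimes; exotic parameter sets may require overriding
  them.
- Very long runs at `record_stride = 1` hold the full EEG, coupling and
  noise records in memory (~100 MB per 1000 s for N = 4).
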