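"""Background noise and deterministic driving signals.

Two inputs perturb the constant drive of each column: an
Ornstein-Uhlenbeck (OU) process, modelling temporally correlated
background synaptic activity, and a deterministic low-frequency signal
(a pure sine or a multi-sine "composed" signal) common to all columns.

OU convention
-------------
The noise obeys ``d xi/dt = -xi/tau + (sqrt(2 D)/tau) * xi_w(t)`` with
``xi_w`` unit-intensity Gaussian white noise.  Under this convention the
stationary standard deviation is ``sqrt(D/tau)`` — about 48.3 Hz at the
default ``D = 350 Hz``, ``tau = 0.15 s`` — and the autocorrelation decays
as ``exp(-|lag|/tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "OUConfig",
    "DriveSpec",
    "ou_stationary_std",
    "ou_step",
    "ou_path",
    "sine_drive",
    "composed_drive",
    "composed_weights",
    "calibrate_composed_amplitude",
    "sample_phases",
]


@dataclass(frozen=True)
class OUConfig:
    """Ornstein-Uhlenbeck noise parameters.

    ``D`` is the noise intensity (Hz, the label used throughout for this
    quantity) and ``tau`` the correlation time (s).
    """

    D: float = 350.0
    tau: float = 0.15

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("noise intensity D must be >= 0")
        if self.tau <= 0:
            raise ValueError("correlation time tau must be > 0")


def ou_stationary_std(cfg: OUConfig) -> float:
    """Stationary standard deviation ``sqrt(D/tau)`` of the OU process (Hz)."""
    return float(np.sqrt(cfg.D / cfg.tau))


def _heun_ou_coefficients(cfg: OUConfig, h: float) -> tuple[float, float]:
    """Decay and noise-gain coefficients of one stochastic Heun step.

    The OU equation is linear, so the Heun update collapses to
    ``xi' = alpha * xi + beta * w`` with ``w ~ N(0, 1)``:
    ``alpha = 1 - h/tau + (h/tau)^2 / 2`` (second-order decay) and
    ``beta = (sqrt(2 D)/tau) * sqrt(h) * (1 - h/(2 tau))`` (the same white
    noise increment applied in predictor and corrector stages).
    """
    q = h / cfg.tau
    alpha = 1.0 - q + 0.5 * q * q
    beta = np.sqrt(2.0 * cfg.D) / cfg.tau * np.sqrt(h) * (1.0 - 0.5 * q)
    return alpha, float(beta)


def ou_step(xi: float, cfg: OUConfig, h: float, w: float) -> float:
    """One stochastic Heun update of the OU noise given a standard normal draw ``w``."""
    if h <= 0:
        raise ValueError("step h must be > 0")
    alpha, beta = _heun_ou_coefficients(cfg, h)
    return alpha * xi + beta * w


def ou_path(
    n: int,
    cfg: OUConfig,
    h: float,
    rng: np.random.Generator,
    xi0: float | None = None,
) -> np.ndarray:
    """Simulate ``n`` Heun steps of the OU process; returns the path (length ``n + 1``).

    ``xi0 = None`` draws the initial value from the stationary distribution,
    avoiding an initialisation transient.
    """
    if h <= 0:
        raise ValueError("step h must be > 0")
    alpha, beta = _heun_ou_coefficients(cfg, h)
    if xi0 is None:
        xi0 = rng.normal(0.0, ou_stationary_std(cfg)) if cfg.D > 0 else 0.0
    w = rng.standard_normal(n)
    # linear recursion xi_{k+1} = alpha xi_k + beta w_k, run as an IIR filter
    driven = lfilter([beta], [1.0, -alpha], w, zi=[alpha * xi0])[0]
    return np.concatenate(([xi0], driven))


@dataclass(frozen=True)
class DriveSpec:
    """Deterministic driving signal common to all columns.

    ``mode`` is one of ``"none"``, ``"sine"`` (``amplitude * sin(2 pi f t)``)
    or ``"composed"`` — a sum of sines on the grid ``f_min : f_step : f_max``
    with exponentially decaying amplitudes and random phases ``X_n`` in
    ``[0, 1)`` (in cycles).
    """

    mode: str = "none"
    amplitude: float = 45.0
    frequency: float = 0.25
    f_min: float = 0.05
    f_max: float = 4.0
    f_step: float = 0.05
    phases: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "sine", "composed"):
            raise ValueError(f"unknown drive mode {self.mode!r}")
        if self.mode == "composed":
            n_min, n_max = _component_range(self.f_min, self.f_max, self.f_step)
            if self.phases is None:
                raise ValueError("composed drive requires phases (see sample_phases)")
            phases = np.asarray(self.phases, dtype=float)
            object.__setattr__(self, "phases", phases)
            if phases.shape != (n_max - n_min + 1,):
                raise ValueError(
                    f"expected {n_max - n_min + 1} phases for grid "
                    f"[{self.f_min}, {self.f_max}] step {self.f_step}, got {phases.shape}"
                )

    def __call__(self, t):
        if self.mode == "none":
            return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
        if self.mode == "sine":
            return sine_drive(t, self.amplitude, self.frequency)
        return composed_drive(t, self)


def _component_range(f_min: float, f_max: float, f_step: float) -> tuple[int, int]:
    """Integer component indices ``n_min, n_max`` with ``f_n = n * f_step``."""
    if f_step <= 0:
        raise ValueError("f_step must be > 0")
    if f_min > f_max:
        raise ValueError("f_min must be <= f_max")
    n_min, n_max = f_min / f_step, f_max / f_step
    for name, val in (("f_min/f_step", n_min), ("f_max/f_step", n_max)):
        if abs(val - round(val)) > 1e-6 * max(1.0, abs(val)):
            raise ValueError(f"{name} = {val} is not an integer")
    return int(round(n_min)), int(round(n_max))


def composed_weights(f_min: float, f_max: float, f_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Component frequencies and relative amplitudes of the composed signal.

    The weight of the component at frequency ``f_n = n * f_step`` is
    ``10 ** (-(f_n - f_min)/(f_max - f_min))``: amplitudes decay by a factor
    of ten from ``f_min`` to ``f_max``.  The degenerate single-component
    grid (``f_min == f_max``) gets weight one.
    """
    n_min, n_max = _component_range(f_min, f_max, f_step)
    n = np.arange(n_min, n_max + 1)
    freqs = n * f_step
    if f_max == f_min:
        return freqs, np.ones_like(freqs)
    return freqs, 10.0 ** (-(freqs - f_min) / (f_max - f_min))


def sine_drive(t, amplitude: float, frequency: float):
    """Pure sinusoidal drive ``amplitude * sin(2 pi f t)`` (Hz)."""
    return amplitude * np.sin(2.0 * np.pi * frequency * np.asarray(t, dtype=float))


def composed_drive(t, spec: DriveSpec):
    """Multi-sine drive: weighted sum of sines with per-component phases.

    ``f(t) = A' * sum_n w_n sin(2 pi (f_n t + X_n))`` with the weights of
    :func:`composed_weights` and phases ``X_n`` in cycles.
    """
    freqs, weights = composed_weights(spec.f_min, spec.f_max, spec.f_step)
    t = np.asarray(t, dtype=float)
    phase = 2.0 * np.pi * (np.multiply.outer(t, freqs) + spec.phases)
    out = spec.amplitude * np.sin(phase) @ weights
    return out if out.ndim else float(out)


def calibrate_composed_amplitude(
    amplitude_sine: float, f_min: float, f_max: float, f_step: float
) -> float:
    """Composed-signal amplitude delivering the power of a sine of given amplitude.

    The phase-averaged mean power of the composed signal is
    ``A'^2 * sum_n w_n^2 / 2``; equating it to the sine's ``A^2 / 2`` gives
    ``A' = A / sqrt(sum_n w_n^2)``.  With the default grid (0.05-4 Hz in
    0.05 Hz steps) and ``A = 45 Hz`` this yields ``A' = 10.76 Hz``.
    """
    _, weights = composed_weights(f_min, f_max, f_step)
    if weights.size == 0:
        raise ValueError("composed drive has no components")
    return float(amplitude_sine / np.sqrt(np.sum(weights**2)))


def sample_phases(count: int, seed) -> np.ndarray:
    """Draw ``count`` uniform phases in ``[0, 1)``; reproducible for a fixed seed."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.random(count)
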