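"""Stochastic Heun integration of the noisy column network.

``simulate`` is the main entry point: it advances the network with the
stochastic Heun predictor-corrector scheme (Euler predictor, trapezoidal
corrector, one shared white-noise increment per step) at a fixed step
``h``, records the per-column EEG observable ``y1 - y2`` together with the
coupling input and the OU noise, and returns a :class:`TimeSeries` whose
provenance fully determines the run.

Reproducibility: the master seed is expanded with ``numpy``'s
``SeedSequence.spawn`` into one child stream per column, in column order,
so the noise is fully determined by ``(seed, N)`` regardless of block
sizes or recording options.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import heun_block
from .drive import DriveSpec, OUConfig, ou_stationary_std
from .model import NetworkState
from .params import ColumnParameters, NetworkConfig

__all__ = [
    "SimulationConfig",
    "TimeSeries",
    "NumericalBlowupError",
    "heun_step",
    "simulate",
    "discard_transient",
    "save_timeseries",
    "load_timeseries",
]

_BLOCK = 200_000  # steps per kernel call; bounds the noise buffer memory


class NumericalBlowupError(RuntimeError):
    """Raised when the state leaves the finite range during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings.

    ``h`` integration step (s), ``duration`` total simulated span (s),
    ``transient`` initial span discarded by the experiment layer (s),
    ``record_stride`` output decimation (1 keeps every step, i.e. a
    1 kHz output rate at the default ``h = 1 ms``).
    """

    h: float = 0.001
    duration: float = 1010.0
    transient: float = 10.0
    seed: int = 0
    record_stride: int = 1
    share_noise: bool = False  # test mode: one OU stream shared by all columns

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if not (self.duration > self.transient >= 0):
            raise ValueError("need duration > transient >= 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.h))

    @property
    def fs(self) -> float:
        return 1.0 / (self.h * self.record_stride)


@dataclass
class TimeSeries:
    """Recorded output of one run.

    ``eeg``, ``coupling`` and ``xi`` have shape ``(n_samples, N)`` and hold
    the per-column EEG observable (mV), coupling input (Hz) and OU noise
    (Hz) on the sample grid ``t0 + arange(n)/fs``.  ``final_state`` is the
    full network state at the end of the run (useful for continuation).
    """

    fs: float
    t0: float
    eeg: np.ndarray
    coupling: np.ndarray | None = None
    xi: np.ndarray | None = None
    final_state: NetworkState | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.eeg.shape[0]

    @property
    def N(self) -> int:
        return self.eeg.shape[1]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def average(self) -> np.ndarray:
        """Column-averaged EEG signal (the electrode-like observable)."""
        return self.eeg.mean(axis=1)

    @property
    def duration(self) -> float:
        return self.n / self.fs


def _spawn_generators(sim: SimulationConfig, N: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(sim.seed).spawn(N)
    if sim.share_noise:
        shared = np.random.default_rng(children[0])
        return [shared] * N
    return [np.random.default_rng(c) for c in children]


def heun_step(
    state: NetworkState,
    t: float,
    h: float,
    params: ColumnParameters,
    net: NetworkConfig,
    ou: OUConfig,
    drive: DriveSpec | None,
    w: np.ndarray,
) -> NetworkState:
    """One stochastic Heun step, written at the Python level.

    This is the readable reference for the compiled block kernel (the two
    agree to rounding error) and is convenient for single-step tests.
    ``w`` holds one standard-normal draw per column; the same draw enters
    predictor and corrector, so with ``D = 0`` the update is plain
    deterministic Heun.
    """
    from .model import sigmoid

    def drift(y, z, xi_val, tt):
        rates = sigmoid(y[:, 1] - y[:, 2], params)
        if net.N > 1:
            coup = (net.K.T @ rates) / (net.N - 1)
        else:
            coup = np.zeros(1)
        posc = drive(tt) if drive is not None else 0.0
        p_exc = net.p_const + coup + posc + xi_val
        dz = np.empty_like(z)
        dz[:, 0] = params.A * params.a * rates - 2 * params.a * z[:, 0] - params.a**2 * y[:, 0]
        dz[:, 1] = (
            params.A * params.a * (p_exc + params.C2 * sigmoid(params.C1 * y[:, 0], params))
            - 2 * params.a * z[:, 1]
            - params.a**2 * y[:, 1]
        )
        dz[:, 2] = (
            params.B * params.b * params.C4 * sigmoid(params.C3 * y[:, 0], params)
            - 2 * params.b * z[:, 2]
            - params.b**2 * y[:, 2]
        )
        return z.copy(), dz

    w = np.asarray(w, dtype=float)
    noise_add = np.sqrt(2.0 * ou.D) / ou.tau * np.sqrt(h) * w
    dy, dz = drift(state.y, state.z, state.xi, t)
    yp = state.y + h * dy
    zp = state.z + h * dz
    xip = state.xi - h * state.xi / ou.tau + noise_add
    dyp, dzp = drift(yp, zp, xip, t + h)
    y1 = state.y + 0.5 * h * (dy + dyp)
    z1 = state.z + 0.5 * h * (dz + dzp)
    xi1 = state.xi - 0.5 * h * (state.xi + xip) / ou.tau + noise_add
    out = NetworkState(y1, z1, xi1, t + h)
    if not (np.all(np.isfinite(y1)) and np.all(np.isfinite(z1))):
        bad = int(np.argwhere(~np.isfinite(y1).all(axis=1))[0][0])
        raise NumericalBlowupError(f"non-finite state in column {bad} at t = {t + h:.3f} s")
    return out


def _provenance(net, params, ou, drive, sim) -> dict:
    def as_dict(obj):
        if obj is None:
            return None
        d = dataclasses.asdict(obj)
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                d[key] = val.tolist()
        return d

    return {
        "network": as_dict(net),
        "parameters": as_dict(params),
        "noise": as_dict(ou),
        "drive": as_dict(drive),
        "simulation": as_dict(sim),
    }


def simulate(
    net: NetworkConfig,
    params: ColumnParameters | None = None,
    ou: OUConfig | None = None,
    drive: DriveSpec | None = None,
    sim: SimulationConfig | None = None,
    initial_state: NetworkState | None = None,
) -> TimeSeries:
    """Run the network for ``sim.duration`` seconds and record its output.

    The initial condition defaults to the all-zero state (its settling is
    absorbed by the transient span discarded downstream); the OU noise is
    initialised from its stationary distribution.  Identical seeds give
    bit-identical outputs.
    """
    params = params or ColumnParameters()
    ou = ou or OUConfig()
    sim = sim or SimulationConfig()
    N = net.N
    n_steps = sim.n_steps
    stride = sim.record_stride
    n_rec = n_steps // stride + 1

    gens = _spawn_generators(sim, N)
    if initial_state is not None:
        if initial_state.y.shape != (N, 3):
            raise ValueError(f"initial state has shape {initial_state.y.shape}, expected ({N}, 3)")
        y = initial_state.y.astype(float).copy()
        z = initial_state.z.astype(float).copy()
        xi = initial_state.xi.astype(float).copy()
    else:
        y = np.zeros((N, 3))
        z = np.zeros((N, 3))
        if ou.D > 0:
            sd = ou_stationary_std(ou)
            if sim.share_noise:
                xi = np.full(N, gens[0].normal(0.0, sd))
            else:
                xi = np.array([g.normal(0.0, sd) for g in gens])
        else:
            xi = np.zeros(N)

    Kn = (net.K.T / (N - 1)).copy() if N > 1 else np.zeros((1, 1))
    noise_gain = float(np.sqrt(2.0 * ou.D) / ou.tau * np.sqrt(sim.h))
    eeg = np.empty((n_rec, N))
    coup_rec = np.empty((n_rec, N))
    xi_rec = np.empty((n_rec, N))

    k0 = 0
    while k0 < n_steps:
        nb = min(_BLOCK, n_steps - k0)
        if ou.D > 0:
            if sim.share_noise:
                Wcol = gens[0].standard_normal(nb)
                W = np.repeat(Wcol[:, None], N, axis=1)
            else:
                W = np.empty((nb, N))
                for i, g in enumerate(gens):
                    W[:, i] = g.standard_normal(nb)
        else:
            W = np.zeros((nb, N))
        t_grid = (k0 + np.arange(nb + 1)) * sim.h
        posc = np.asarray(drive(t_grid), dtype=float) if drive is not None else np.zeros(nb + 1)
        heun_block(
            y, z, xi, Kn, float(net.p_const), posc, W, sim.h, ou.tau, noise_gain,
            k0, nb,
            params.A, params.B, params.a, params.b,
            params.C1, params.C2, params.C3, params.C4,
            params.e0, params.v0, params.r,
            stride, eeg, coup_rec, xi_rec,
        )
        if not np.all(np.isfinite(y)):
            bad = int(np.argwhere(~np.isfinite(y).all(axis=1))[0][0])
            raise NumericalBlowupError(
                f"non-finite state in column {bad} near t = {(k0 + nb) * sim.h:.3f} s"
            )
        k0 += nb

    # the kernel records states at steps < n_steps; add the terminal sample
    if n_steps % stride == 0:
        eeg[-1] = y[:, 1] - y[:, 2]
        from .model import coupling_inputs

        final = NetworkState(y, z, xi, n_steps * sim.h)
        coup_rec[-1] = coupling_inputs(final, net, params)
        xi_rec[-1] = xi

    return TimeSeries(
        fs=sim.fs,
        t0=0.0,
        eeg=eeg,
        coupling=coup_rec,
        xi=xi_rec,
        final_state=NetworkState(y, z, xi, n_steps * sim.h),
        provenance=_provenance(net, params, ou, drive, sim),
    )


def discard_transient(ts: TimeSeries, t_cut: float) -> TimeSeries:
    """Drop samples with ``t < t_cut``; the first kept sample has ``t >= t_cut``."""
    if t_cut >= ts.t0 + ts.duration:
        raise ValueError(f"t_cut = {t_cut} s is not inside the series")
    if t_cut <= ts.t0:
        return ts
    keep = ts.t >= t_cut
    start = int(np.argmax(keep))
    prov = dict(ts.provenance)
    prov["transient_cut_s"] = t_cut
    return TimeSeries(
        fs=ts.fs,
        t0=float(ts.t[start]),
        eeg=ts.eeg[start:],
        coupling=None if ts.coupling is None else ts.coupling[start:],
        xi=None if ts.xi is None else ts.xi[start:],
        final_state=ts.final_state,
        provenance=prov,
    )


def save_timeseries(ts: TimeSeries, path) -> None:
    """Write the EEG channels as headered plain text (lossless round trip)."""
    meta = {"fs": ts.fs, "t0": ts.t0, "n": ts.n, "N": ts.N, "provenance": ts.provenance}
    data = np.column_stack([ts.t, ts.eeg])
    header = "neuromass-timeseries v1\n" + json.dumps(meta) + "\nt_s " + " ".join(
        f"eeg_{i}_mV" for i in range(ts.N)
    )
    np.savetxt(path, data, fmt="%.17g", header=header)


def load_timeseries(path) -> TimeSeries:
    """Read a series written by :func:`save_timeseries`."""
    with open(path) as fh:
        lines = [fh.readline() for _ in range(3)]
    if "neuromass-timeseries" not in lines[0]:
        raise ValueError(f"{path} is not a neuromass timeseries file")
    meta = json.loads(lines[1].lstrip("# "))
    data = np.loadtxt(path)
    data = data.reshape(meta["n"], -1)
    return TimeSeries(
        fs=meta["fs"], t0=meta["t0"], eeg=data[:, 1:], provenance=meta.get("provenance", {})
    )
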