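"""Deterministic equations of the Jansen-Rit column and its network couplings.

State convention: each column carries three mean postsynaptic potentials
``y0, y1, y2`` (mV) and their time derivatives ``z0, z1, z2`` (mV/s), i.e.
the second-order synaptic dynamics written in six-dimensional first-order
form.  ``y0`` is the pyramidal output potential feeding both interneuron
populations; ``y1`` and ``y2`` are the excitatory and inhibitory potentials
entering the pyramidal population.  The EEG-like observable of a column is
``y1 - y2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ColumnParameters, NetworkConfig

__all__ = [
    "ColumnState",
    "NetworkState",
    "sigmoid",
    "sigmoid_derivative",
    "column_derivatives",
    "coupling_inputs",
    "total_pyramidal_input",
    "eeg_observable",
]


@dataclass
class ColumnState:
    """Six-dimensional state of one column (potentials in mV, derivatives in mV/s)."""

    y0: float = 0.0
    y1: float = 0.0
    y2: float = 0.0
    z0: float = 0.0
    z1: float = 0.0
    z2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.y0, self.y1, self.y2, self.z0, self.z1, self.z2])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ColumnState":
        return cls(*(float(v) for v in np.asarray(x, dtype=float)))


@dataclass
class NetworkState:
    """State of the whole network at time ``t``.

    ``y`` and ``z`` have shape ``(N, 3)`` (columns x potentials), ``xi`` has
    shape ``(N,)`` and holds each column's Ornstein-Uhlenbeck noise value (Hz).
    """

    y: np.ndarray
    z: np.ndarray
    xi: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, N: int, t: float = 0.0) -> "NetworkState":
        return cls(y=np.zeros((N, 3)), z=np.zeros((N, 3)), xi=np.zeros(N), t=t)

    @property
    def N(self) -> int:
        return self.y.shape[0]

    def column(self, i: int) -> ColumnState:
        return ColumnState(*self.y[i], *self.z[i])

    def copy(self) -> "NetworkState":
        return NetworkState(self.y.copy(), self.z.copy(), self.xi.copy(), self.t)


def sigmoid(y, params: ColumnParameters = ColumnParameters()):
    """Population potential-to-rate sigmoid (1/s).

    ``Sigm(y) = 2 e0 / (1 + exp(r (v0 - y)))``: bounded in ``(0, 2 e0)``,
    equal to ``e0`` at ``y = v0``.  Accepts scalars or arrays.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("sigmoid input must be finite")
    out = 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - y)))
    return out if out.ndim else float(out)

def sigmoid_derivative(y, params: ColumnParameters = ColumnParameters()):
    """d Sigm / dy, expressed through the sigmoid itself:
    ``r * Sigm(y) * (1 - Sigm(y) / (2 e0))``."""
    s = sigmoid(y, params)
    return params.r * s * (1.0 - s / (2.0 * params.e0))


def column_derivatives(
    state: ColumnState, p_exc: float, params: ColumnParameters = ColumnParameters()
) -> ColumnState:
    """Time derivative of a single column's state.

    ``p_exc`` is the total excitatory input rate (Hz) reaching the pyramidal
    population from outside the column (constant + coupling + drive + noise).
    It may be transiently negative under noise; the equations are linear in
    ``p_exc`` and no rectification is applied.
    """
    if not np.isfinite(p_exc):
        raise ValueError("p_exc must be finite")
    P = params
    s_pyr = sigmoid(state.y1 - state.y2, P)
    dz0 = P.A * P.a * s_pyr - 2.0 * P.a * state.z0 - P.a**2 * state.y0
    dz1 = (
        P.A * P.a * (p_exc + P.C2 * sigmoid(P.C1 * state.y0, P))
        - 2.0 * P.a * state.z1
        - P.a**2 * state.y1
    )
    dz2 = P.B * P.b * P.C4 * sigmoid(P.C3 * state.y0, P) - 2.0 * P.b * state.z2 - P.b**2 * state.y2
    return ColumnState(state.z0, state.z1, state.z2, dz0, dz1, dz2)


def coupling_inputs(
    state: NetworkState, net: NetworkConfig, params: ColumnParameters = ColumnParameters()
) -> np.ndarray:
    """Excitatory input rate each column receives from the others (Hz).

    Column ``i`` receives ``(1/(N-1)) * sum_j K[j, i] * Sigm(y1_j - y2_j)``;
    the normalisation by the number of afferents keeps the drive bounded as
    the network grows.  Returns zeros for a single column.
    """
    if state.N != net.N:
        raise ValueError(f"state has {state.N} columns but network expects {net.N}")
    if net.N == 1:
        return np.zeros(1)
    rates = sigmoid(state.y[:, 1] - state.y[:, 2], params)
    return (net.K.T @ rates) / (net.N - 1)


def total_pyramidal_input(
    t: float,
    i: int,
    state: NetworkState,
    net: NetworkConfig,
    drive=None,
    params: ColumnParameters = ColumnParameters(),
) -> float:
    """Total external excitatory input to column ``i``'s pyramidal population (Hz).

    Sum of the constant component, the coupling input, the deterministic
    drive evaluated at ``t`` (if any) and the column's current noise value.
    """
    p = net.p_const + float(coupling_inputs(state, net, params)[i]) + float(state.xi[i])
    if drive is not None:
        p += drive(t)
    return p


def eeg_observable(state: NetworkState) -> tuple[np.ndarray, float]:
    """Per-column EEG-like signal ``y1 - y2`` (mV) and its unweighted column average."""
    per_column = state.y[:, 1] - state.y[:, 2]
    return per_column, float(per_column.mean())
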