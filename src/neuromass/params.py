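"""Model parameters for Jansen-Rit cortical columns and their networks.

A cortical column is described by three interacting neuronal populations
(pyramidal cells, excitatory and inhibitory interneurons).  The constants
collected in :class:`ColumnParameters` are the classic Jansen-Rit set:
synaptic gains ``A``/``B`` (mV), inverse synaptic time constants ``a``/``b``
(1/s), intra-column connectivity constants ``C1``-``C4``, and the three
parameters of the sigmoidal potential-to-rate function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ColumnParameters", "NetworkConfig", "canonical_parameters"]


@dataclass(frozen=True)
class ColumnParameters:
    """Constants of a single Jansen-Rit cortical column.

    Defaults are the canonical Jansen-Rit values, for which the
    single-column model has its well-known bifurcation structure
    (alpha-band Hopf bifurcation near 89.8 Hz of constant input).

    Attributes
    ----------
    A, B : float
        Maximum excitatory / inhibitory postsynaptic potential amplitude (mV).
    a, b : float
        Inverse time constants of the excitatory / inhibitory synaptic
        kernels (1/s); they lump dendritic and propagation delays.
    C1, C2, C3, C4 : float
        Dimensionless intra-column connectivity constants.
    e0 : float
        Half of the maximum population firing rate (1/s).
    v0 : float
        Membrane potential of half-maximal firing (mV).
    r : float
        Steepness of the sigmoid (1/mV).
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    C1: float = 135.0
    C2: float = 0.8 * 135.0
    C3: float = 0.25 * 135.0
    C4: float = 0.25 * 135.0
    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56

    def __post_init__(self) -> None:
        for name in ("A", "B", "a", "b", "C1", "C2", "C3", "C4", "e0", "v0", "r"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")
        if self.C2 > self.C1 or self.C3 != self.C4:
            warnings.warn(
                "non-canonical connectivity constants: expected C2 <= C1 and C3 == C4",
                stacklevel=2,
            )


def canonical_parameters() -> ColumnParameters:
    """Return the canonical Jansen-Rit parameter set."""
    return ColumnParameters()


@dataclass(frozen=True)
class NetworkConfig:
    """All-to-all network of identical columns.

    Attributes
    ----------
    N : int
        Number of columns (>= 1).
    K : numpy.ndarray
        ``N x N`` matrix of inter-column coupling strengths (dimensionless,
        nonnegative, zero diagonal).  Entry ``K[j, i]`` scales the firing
        rate of column ``j`` as seen by column ``i``.
    p_const : float
        Constant component of the external excitatory input (Hz).
    """

    N: int = 4
    K: np.ndarray = field(default=None)  # type: ignore[assignment]
    p_const: float = 75.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.p_const < 0:
            raise ValueError("p_const must be nonnegative")
        K = self.K
        if K is None:
            K = homogeneous_coupling(self.N, 15.0)
            object.__setattr__(self, "K", K)
        K = np.asarray(K, dtype=float)
        object.__setattr__(self, "K", K)
        if K.shape != (self.N, self.N):
            raise ValueError(f"K must be {self.N}x{self.N}, got {K.shape}")
        if np.any(np.diag(K) != 0):
            raise ValueError("K must have zero diagonal (no self-connectivity)")
        if np.any(K < 0):
            raise ValueError("K must be nonnegative")

    @classmethod
    def homogeneous(cls, N: int, K: float, p_const: float) -> "NetworkConfig":
        """Homogeneous all-to-all network: every off-diagonal coupling equals ``K``."""
        return cls(N=N, K=homogeneous_coupling(N, K), p_const=p_const)

    @classmethod
    def single_column(cls, p_const: float = 90.0) -> "NetworkConfig":
        """A single uncoupled column."""
        return cls(N=1, K=np.zeros((1, 1)), p_const=p_const)


def homogeneous_coupling(N: int, K: float) -> np.ndarray:
    """Build the homogeneous all-to-all coupling matrix with strength ``K``."""
    M = np.full((N, N), float(K))
    np.fill_diagonal(M, 0.0)
    return M
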