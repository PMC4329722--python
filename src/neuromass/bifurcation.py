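"""Deterministic bifurcation analysis of the single Jansen-Rit column.

With only a constant input ``p`` the column has a one-dimensional
equilibrium condition: writing ``y = y1 - y2`` for the pyramidal membrane
potential, the steady state satisfies

    y = (A/a) (p + C2 Sigm(C1 y0*)) - (B/b) C4 Sigm(C3 y0*),
    y0* = (A/a) Sigm(y),

which is solved by dense bracketing plus Brent root refinement.  Linear
stability comes from the analytic Jacobian of the six-dimensional
first-order system.  The module locates the two Hopf bifurcations that
delimit the alpha limit cycle (near 89.8 and 315.7 Hz of input for the
canonical parameters) and, by direct simulation with continuation initial
conditions, the coexistence window of the large-amplitude low-frequency
"spiky" cycle (roughly 113.6-137.4 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import periodogram

from .drive import OUConfig
from .model import ColumnState, NetworkState, column_derivatives, sigmoid, sigmoid_derivative
from .params import ColumnParameters, NetworkConfig
from .simulate import SimulationConfig, simulate

__all__ = [
    "Equilibrium",
    "AttractorLabel",
    "HopfPoint",
    "ClassifierThresholds",
    "fixed_points",
    "jacobian",
    "jacobian_eigenvalues",
    "hopf_scan",
    "classify_attractor",
    "coexistence_boundaries",
]

_Y_BRACKET = (-50.0, 50.0)
_SCAN_POINTS = 2001


@dataclass
class Equilibrium:
    """A fixed point of the single column at constant input ``p_exc``."""

    state: ColumnState
    p_exc: float
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def y(self) -> float:
        """Pyramidal potential ``y1 - y2`` at the equilibrium (mV)."""
        return self.state.y1 - self.state.y2

    @property
    def leading_real(self) -> float:
        return float(self.eigenvalues[0].real)


@dataclass(frozen=True)
class HopfPoint:
    """Input level where a complex eigenvalue pair crosses the imaginary axis."""

    p_exc: float
    frequency_hz: float  # imaginary part / 2 pi at the crossing


@dataclass(frozen=True)
class ClassifierThresholds:
    """Attractor classification thresholds (see :func:`classify_attractor`)."""

    eps_fixed_point: float = 0.1  # peak-to-peak below this (mV): fixed point
    f_split: float = 6.0  # dominant frequency below this (Hz) ...
    amp_split: float = 8.0  # ... together with peak-to-peak above this (mV): spiky
    f_floor: float = 0.5  # ignore spectral content below this (Hz)


@dataclass(frozen=True)
class AttractorLabel:
    """Classification of a deterministic trajectory."""

    label: str  # fixed_point | alpha_cycle | spiky_cycle
    dominant_frequency_hz: float
    peak_to_peak_mv: float


def _equilibrium_residual(y: float, p_exc: float, P: ColumnParameters) -> float:
    y0 = (P.A / P.a) * sigmoid(y, P)
    return (
        (P.A / P.a) * (p_exc + P.C2 * sigmoid(P.C1 * y0, P))
        - (P.B / P.b) * P.C4 * sigmoid(P.C3 * y0, P)
        - y
    )


def _lift(y: float, p_exc: float, P: ColumnParameters) -> ColumnState:
    """Lift a root of the scalar reduction to the full six-dimensional state."""
    y0 = (P.A / P.a) * sigmoid(y, P)
    y1 = (P.A / P.a) * (p_exc + P.C2 * sigmoid(P.C1 * y0, P))
    y2 = (P.B / P.b) * P.C4 * sigmoid(P.C3 * y0, P)
    return ColumnState(y0, y1, y2, 0.0, 0.0, 0.0)


def fixed_points(p_exc: float, params: ColumnParameters | None = None) -> list[Equilibrium]:
    """All equilibria of the single column at input ``p_exc``, sorted by ``y1 - y2``.

    Each returned equilibrium carries the eigenvalues of the linearisation,
    sorted by real part in descending order.
    """
    if p_exc < 0:
        raise ValueError("p_exc must be >= 0")
    P = params or ColumnParameters()
    ys = np.linspace(*_Y_BRACKET, _SCAN_POINTS)
    vals = np.array([_equilibrium_residual(y, p_exc, P) for y in ys])
    roots: list[float] = []
    for i in range(len(ys) - 1):
        if vals[i] == 0.0:
            roots.append(float(ys[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                brentq(_equilibrium_residual, ys[i], ys[i + 1], args=(p_exc, P), xtol=1e-13)
            )
    if vals[-1] == 0.0:
        roots.append(float(ys[-1]))
    if not roots:
        raise RuntimeError(f"no equilibrium found in y bracket {_Y_BRACKET} at p = {p_exc}")
    eqs = []
    for y in sorted(roots):
        eq = Equilibrium(state=_lift(y, p_exc, P), p_exc=p_exc)
        eq.eigenvalues = jacobian_eigenvalues(eq, P)
        eqs.append(eq)
    return eqs


def jacobian(eq: Equilibrium, params: ColumnParameters | None = None) -> np.ndarray:
    """Analytic Jacobian of the six-dimensional column system at an equilibrium.

    State ordering ``(y0, y1, y2, z0, z1, z2)``; the nonlinear entries use
    ``Sigm'(y) = r Sigm(y) (1 - Sigm(y)/(2 e0))``.
    """
    P = params or ColumnParameters()
    s = eq.state
    J = np.zeros((6, 6))
    J[0, 3] = J[1, 4] = J[2, 5] = 1.0
    dpyr = sigmoid_derivative(s.y1 - s.y2, P)
    J[3, 0] = -P.a**2
    J[3, 1] = P.A * P.a * dpyr
    J[3, 2] = -P.A * P.a * dpyr
    J[3, 3] = -2.0 * P.a
    J[4, 0] = P.A * P.a * P.C2 * P.C1 * sigmoid_derivative(P.C1 * s.y0, P)
    J[4, 1] = -P.a**2
    J[4, 4] = -2.0 * P.a
    J[5, 0] = P.B * P.b * P.C4 * P.C3 * sigmoid_derivative(P.C3 * s.y0, P)
    J[5, 2] = -P.b**2
    J[5, 5] = -2.0 * P.b
    return J


def jacobian_eigenvalues(eq: Equilibrium, params: ColumnParameters | None = None) -> np.ndarray:
    """Eigenvalues of the linearisation, sorted by real part, descending."""
    ev = np.linalg.eigvals(jacobian(eq, params))
    return ev[np.argsort(-ev.real)]


def _leading_complex_real(p_exc: float, params: ColumnParameters) -> tuple[float, float]:
    """Largest real part over all equilibria's complex eigenvalue pairs.

    Returns ``(real part, |imaginary part|)`` of the leading complex pair.
    Real eigenvalues are ignored: a Hopf point is a crossing of a complex
    pair, and the saddle branch's positive real eigenvalue would otherwise
    mask it.
    """
    best = (-np.inf, 0.0)
    for eq in fixed_points(p_exc, params):
        pairs = eq.eigenvalues[np.abs(eq.eigenvalues.imag) > 1e-9]
        if pairs.size:
            lead = pairs[0]
            if lead.real > best[0]:
                best = (float(lead.real), float(abs(lead.imag)))
    if not np.isfinite(best[0]):
        raise RuntimeError(f"no complex eigenvalue pair at p = {p_exc}")
    return best


def hopf_scan(
    p_lo: float,
    p_hi: float,
    params: ColumnParameters | None = None,
    tol: float = 0.01,
    grid_step: float = 1.0,
) -> list[HopfPoint]:
    """Locate Hopf bifurcations of the equilibrium branch in ``[p_lo, p_hi]``.

    The leading complex-pair real part is evaluated on a coarse grid; each
    sign change is refined by bisection to ``tol`` (Hz of input).  Returns
    an empty list when no crossing exists in the range.
    """
    if p_lo >= p_hi:
        raise ValueError("need p_lo < p_hi")
    P = params or ColumnParameters()
    grid = np.arange(p_lo, p_hi + grid_step, grid_step)
    grid[-1] = min(grid[-1], p_hi)
    re = np.array([_leading_complex_real(p, P)[0] for p in grid])
    points = []
    for i in range(len(grid) - 1):
        if re[i] == 0.0 or re[i] * re[i + 1] >= 0:
            continue
        lo, hi = float(grid[i]), float(grid[i + 1])
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _leading_complex_real(mid, P)[0] * re[i] > 0:
                lo = mid
            else:
                hi = mid
        p_star = 0.5 * (lo + hi)
        points.append(HopfPoint(p_exc=p_star, frequency_hz=_leading_complex_real(p_star, P)[1] / (2 * np.pi)))
    return points


def classify_attractor(
    trajectory: np.ndarray,
    fs: float,
    thresholds: ClassifierThresholds | None = None,
) -> AttractorLabel:
    """Label a deterministic, transient-free EEG trajectory.

    A near-constant signal (peak-to-peak below ``eps_fixed_point``) is a
    fixed point.  Otherwise the dominant frequency (spectral peak above
    ``f_floor``) separates the large, slow spiky cycle (dominant frequency
    below ``f_split`` *and* peak-to-peak above ``amp_split``) from the
    alpha cycle.
    """
    th = thresholds or ClassifierThresholds()
    x = np.asarray(trajectory, dtype=float)
    if x.size / fs < 10.0:
        raise ValueError("need at least 10 s of trajectory to classify")
    ptp = float(x.max() - x.min())
    if ptp < th.eps_fixed_point:
        return AttractorLabel("fixed_point", 0.0, ptp)
    f, P = periodogram(x, fs)
    mask = f > th.f_floor
    f_dom = float(f[mask][np.argmax(P[mask])])
    if f_dom < th.f_split and ptp > th.amp_split:
        return AttractorLabel("spiky_cycle", f_dom, ptp)
    return AttractorLabel("alpha_cycle", f_dom, ptp)


def _run_inventory(
    p_exc: float,
    initial_states: list[np.ndarray],
    params: ColumnParameters,
    run_s: float,
    settle_s: float,
    thresholds: ClassifierThresholds | None,
) -> tuple[list[AttractorLabel], list[np.ndarray]]:
    """Deterministically integrate a batch of initial conditions at input ``p_exc``.

    The batch runs as one network of uncoupled, noise-free columns (one per
    initial condition), which shares a single compiled integrator call.
    Returns the labels (classified on the trajectory after ``settle_s``)
    and the final six-dimensional states for continuation.
    """
    m = len(initial_states)
    net = NetworkConfig(N=m, K=np.zeros((m, m)), p_const=p_exc)
    init = NetworkState(
        y=np.array([s[:3] for s in initial_states]),
        z=np.array([s[3:] for s in initial_states]),
        xi=np.zeros(m),
    )
    sim = SimulationConfig(h=0.001, duration=run_s, transient=0.0, seed=0)
    ts = simulate(net, params, OUConfig(D=0.0, tau=0.15), None, sim, initial_state=init)
    cut = int(settle_s * ts.fs)
    labels = [classify_attractor(ts.eeg[cut:, i], ts.fs, thresholds) for i in range(m)]
    finals = [
        np.concatenate([ts.final_state.y[i], ts.final_state.z[i]]) for i in range(m)
    ]
    return labels, finals


def _ic_library(p_exc: float, params: ColumnParameters) -> list[np.ndarray]:
    """Initial conditions probed at each input level.

    The equilibria themselves, +/-2 and +/-10 mV kicks of ``y1`` off each
    equilibrium (these find the alpha cycle around the unstable focus), and
    the rest (all-zero) state, which falls into the spiky basin once the
    lower stable node has vanished; a continuation state from a
    neighbouring spiky orbit is appended by the caller when available.
    """
    ics = []
    for eq in fixed_points(p_exc, params):
        base = eq.state.as_array()
        ics.append(base.copy())
        for d in (2.0, -2.0, 10.0, -10.0):
            kicked = base.copy()
            kicked[1] += d
            ics.append(kicked)
    ics.append(np.zeros(6))
    return ics


def coexistence_boundaries(
    params: ColumnParameters | None = None,
    search: tuple[float, float] = (105.0, 150.0),
    tol: float = 0.1,
    run_s: float = 50.0,
    settle_s: float = 10.0,
    thresholds: ClassifierThresholds | None = None,
) -> tuple[float, float]:
    """Input range over which the spiky attractor exists, by simulation.

    A seed run near the middle of ``search`` must find a spiky trajectory;
    the lower and upper existence boundaries are then bisected to ``tol``,
    carrying the final state of the last spiky orbit along as a
    continuation initial condition (this is what tracks the attractor
    reliably near its fold).  For canonical parameters the window is
    approximately (113.6, 137.4) Hz.
    """
    P = params or ColumnParameters()
    p_seed = 0.5 * (search[0] + search[1])

    def inventory(p, cont):
        ics = _ic_library(p, P)
        if cont is not None:
            ics.append(cont)
        labels, finals = _run_inventory(p, ics, P, run_s, settle_s, thresholds)
        spiky_state = None
        for lab, fin in zip(labels, finals):
            if lab.label == "spiky_cycle":
                spiky_state = fin
                break
        return labels, spiky_state

    labels, spiky = inventory(p_seed, None)
    if spiky is None:
        raise RuntimeError(
            f"no spiky attractor at seed input {p_seed} Hz; inventory: "
            + ", ".join(l.label for l in labels)
        )

    def bisect(lo, hi, spiky_at_lo, cont_state):
        """Boundary between spiky-present and spiky-absent inputs."""
        cont = cont_state
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            _, found = inventory(mid, cont)
            present = found is not None
            if present:
                cont = found
            if present == spiky_at_lo:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    onset = bisect(search[0], p_seed, False, spiky)
    offset = bisect(p_seed, search[1], True, spiky)
    return onset, offset
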