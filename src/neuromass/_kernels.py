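"""Inner integration loop of the stochastic Heun scheme.

The block kernel advances the whole network (column states plus per-column
OU noise) step by step, recording the EEG observable, the coupling input
and the noise at a fixed stride.  The same source is compiled with numba
when available and executed as plain Python otherwise; both paths produce
bit-identical results because the arithmetic is identical.

Conventions baked into the kernel (mirrored by the Python-level
``heun_step`` used in tests):

* Euler predictor, trapezoidal corrector; the single white-noise increment
  ``noise_gain * W[k, i]`` of a step is shared by both stages, so with
  ``D = 0`` the scheme reduces to deterministic Heun.
* The deterministic drive is evaluated at ``t`` in the predictor and at
  ``t + h`` in the corrector (``posc`` holds the drive on the step grid).
* The OU noise enters only through the total pyramidal input of the
  ``y1`` equation.
"""

from __future__ import annotations

import numpy as np


def _heun_block_impl(
    y,
    z,
    xi,
    Kn,
    p_const,
    posc,
    W,
    h,
    tau,
    noise_gain,
    k0,
    nb,
    A,
    Bp,
    a,
    b,
    C1,
    C2,
    C3,
    C4,
    e0,
    v0,
    r,
    stride,
    eeg,
    coup_rec,
    xi_rec,
):
    """Advance ``nb`` steps from global step ``k0``, updating state in place.

    ``Kn`` is the pre-normalised coupling matrix ``K.T / (N - 1)`` (zeros
    for ``N = 1``); ``posc`` is the deterministic drive sampled on the
    block's step grid (``nb + 1`` values, ``posc[kk]`` at step ``k0 + kk``);
    ``W`` is the block of standard-normal draws, shape ``(nb, N)``;
    ``noise_gain = sqrt(2 D)/tau * sqrt(h)``.  The state at time ``k * h``
    is recorded at sample index ``k // stride`` whenever ``k % stride == 0``.
    """
    N = y.shape[0]
    two_e0 = 2.0 * e0
    aa = a * a
    bb = b * b
    rates = np.empty(N)
    coup = np.empty(N)
    dz = np.empty((N, 3))
    yp = np.empty((N, 3))
    zp = np.empty((N, 3))
    xip = np.empty(N)
    dzp = np.empty((N, 3))
    for kk in range(nb):
        k = k0 + kk
        for i in range(N):
            rates[i] = two_e0 / (1.0 + np.exp(r * (v0 - (y[i, 1] - y[i, 2]))))
        for i in range(N):
            s = 0.0
            for j in range(N):
                s += Kn[i, j] * rates[j]
            coup[i] = s
        if k % stride == 0:
            m = k // stride
            for i in range(N):
                eeg[m, i] = y[i, 1] - y[i, 2]
                coup_rec[m, i] = coup[i]
                xi_rec[m, i] = xi[i]
        # predictor (Euler stage)
        for i in range(N):
            p_exc = p_const + coup[i] + posc[kk] + xi[i]
            s0 = two_e0 / (1.0 + np.exp(r * (v0 - C1 * y[i, 0])))
            s3 = two_e0 / (1.0 + np.exp(r * (v0 - C3 * y[i, 0])))
            dz[i, 0] = A * a * rates[i] - 2.0 * a * z[i, 0] - aa * y[i, 0]
            dz[i, 1] = A * a * (p_exc + C2 * s0) - 2.0 * a * z[i, 1] - aa * y[i, 1]
            dz[i, 2] = Bp * b * C4 * s3 - 2.0 * b * z[i, 2] - bb * y[i, 2]
            for c in range(3):
                yp[i, c] = y[i, c] + h * z[i, c]
                zp[i, c] = z[i, c] + h * dz[i, c]
            xip[i] = xi[i] - h * xi[i] / tau + noise_gain * W[kk, i]
        # corrector (trapezoidal stage) at the predicted state, t + h
        for i in range(N):
            rates[i] = two_e0 / (1.0 + np.exp(r * (v0 - (yp[i, 1] - yp[i, 2]))))
        for i in range(N):
            s = 0.0
            for j in range(N):
                s += Kn[i, j] * rates[j]
            coup[i] = s
        for i in range(N):
            p_exc = p_const + coup[i] + posc[kk + 1] + xip[i]
            s0 = two_e0 / (1.0 + np.exp(r * (v0 - C1 * yp[i, 0])))
            s3 = two_e0 / (1.0 + np.exp(r * (v0 - C3 * yp[i, 0])))
            dzp[i, 0] = A * a * rates[i] - 2.0 * a * zp[i, 0] - aa * yp[i, 0]
            dzp[i, 1] = A * a * (p_exc + C2 * s0) - 2.0 * a * zp[i, 1] - aa * yp[i, 1]
            dzp[i, 2] = Bp * b * C4 * s3 - 2.0 * b * zp[i, 2] - bb * yp[i, 2]
            for c in range(3):
                y[i, c] = y[i, c] + 0.5 * h * (z[i, c] + zp[i, c])
                z[i, c] = z[i, c] + 0.5 * h * (dz[i, c] + dzp[i, c])
            xi[i] = xi[i] - 0.5 * h * (xi[i] + xip[i]) / tau + noise_gain * W[kk, i]


try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit

    heun_block = njit(cache=True)(_heun_block_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    heun_block = _heun_block_impl
    HAVE_NUMBA = False
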