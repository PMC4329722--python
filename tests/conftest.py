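"""Shared fixtures.

The session-scoped simulation fixtures run once and are reused by both the
module tests and the acceptance checks; they use 300 s post-transient
spans (the reference protocol uses 1000 s, which only narrows the
stochastic error bars without changing any of the qualitative outcomes
asserted here).
"""

from __future__ import annotations

import numpy as np
import pytest

import neuromass as nm


@pytest.fixture(scope="session")
def params() -> nm.ColumnParameters:
    return nm.ColumnParameters()


@pytest.fixture(scope="session")
def single_column_stationary():
    """310 s single-column run at p_const = 90 Hz with reference noise."""
    spec = nm.ExperimentSpec.single_column(duration=310.0, seeds=(1,))
    return nm.run_stationary(spec)


@pytest.fixture(scope="session")
def coupled_stationary():
    """310 s four-column run (K = 15, p_const = 75 Hz)."""
    spec = nm.ExperimentSpec.coupled(duration=310.0, seeds=(1,))
    return nm.run_stationary(spec)


@pytest.fixture(scope="session")
def driven_result():
    """Matched stationary / sine / composed spectra, 10 phase realisations."""
    spec = nm.ExperimentSpec(
        scenario="sine_driven", duration=310.0, seeds=(1,), n_phase_realizations=10
    )
    return nm.run_driven(spec)


@pytest.fixture(scope="session")
def frequency_response_map():
    """Two-point driving-frequency sweep (0.25 Hz and 10 Hz), two seeds."""
    spec = nm.ExperimentSpec(
        scenario="response_map_frequency", duration=310.0, seeds=(1, 2), sweep=(0.25, 10.0)
    )
    return nm.run_response_map(spec)


def notched_band_mean_db(rm: nm.ResponseMap, row: int, f_lo: float, f_hi: float,
                         notch_center: float | None = None, notch_half: float = 0.5) -> float:
    """Mean dB change in a band, optionally notching the drive line and harmonic."""
    f = rm.frequencies
    m = (f >= f_lo) & (f <= f_hi)
    if notch_center is not None:
        for c in (notch_center, 2 * notch_center):
            m &= ~((f > c - notch_half) & (f < c + notch_half))
    return float(np.nanmean(rm.db[row][m]))
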