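"""Unit tests for the column equations, sigmoid, coupling and observable."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neuromass as nm
from neuromass.model import ColumnState, NetworkState


class TestSigmoid:
    def test_half_activation_and_saturation(self, params):
        # at y = v0 the rate is half the maximum; far above it saturates at 2 e0
        assert nm.sigmoid(params.v0, params) == pytest.approx(params.e0)
        assert nm.sigmoid(1e3, params) == pytest.approx(2 * params.e0)

    def test_value_at_zero_potential(self, params):
        # direct scalar evaluation of the rate function at y = 0
        expected = 2 * 2.5 / (1 + np.exp(0.56 * 6.0))
        assert nm.sigmoid(0.0, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1678, abs=5e-5)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
    def test_bounded_interval(self, y):
        # mathematically (0, 2 e0); in floats the upper bound is attained
        # once exp underflows, so the numerical contract is half-open
        s = nm.sigmoid(y)
        assert 0.0 < s <= 5.0

    def test_monotone_on_dense_grid(self, params):
        y = np.linspace(-40, 40, 4001)
        assert np.all(np.diff(nm.sigmoid(y, params)) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            nm.sigmoid(np.nan)

    def test_derivative_matches_finite_difference(self, params):
        y = np.linspace(-20, 20, 41)
        eps = 1e-6
        fd = (nm.sigmoid(y + eps, params) - nm.sigmoid(y - eps, params)) / (2 * eps)
        assert np.allclose(nm.sigmoid_derivative(y, params), fd, rtol=1e-7)


class TestColumnDerivatives:
    def test_zero_state_hand_values(self, params):
        # hand evaluation of the y1 and y2 equations at the all-zero state
        s0 = nm.sigmoid(0.0, params)
        d = nm.column_derivatives(ColumnState(), p_exc=90.0, params=params)
        assert d.z1 == pytest.approx(325.0 * (90.0 + 108.0 * s0), rel=1e-12)
        assert d.z1 == pytest.approx(3.514e4, rel=1e-3)
        d0 = nm.column_derivatives(ColumnState(), p_exc=0.0, params=params)
        assert d0.z2 == pytest.approx(22.0 * 50.0 * 33.75 * s0, rel=1e-12)
        assert d0.z2 == pytest.approx(6.23e3, rel=1e-3)

    @pytest.mark.parametrize("p_exc", [0.0, 50.0, 90.0, 200.0, 400.0])
    def test_vanishes_at_solved_equilibria(self, params, p_exc):
        for eq in nm.fixed_points(p_exc, params):
            d = nm.column_derivatives(eq.state, p_exc, params).as_array()
            assert np.max(np.abs(d)) < 1e-9 * max(1.0, abs(eq.state.y1))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            nm.column_derivatives(ColumnState(), np.inf)


class TestCoupling:
    def test_zero_matrix_gives_zero(self, params):
        net = nm.NetworkConfig(N=3, K=np.zeros((3, 3)), p_const=75.0)
        state = NetworkState.zeros(3)
        state.y[:, 1] = 5.0
        assert np.all(nm.coupling_inputs(state, net, params) == 0)

    def test_homogeneous_normalisation_cancels(self, params):
        # identical columns at y1 - y2 = v0: each receives K * e0 = 37.5 Hz
        net = nm.NetworkConfig.homogeneous(4, 15.0, 75.0)
        state = NetworkState.zeros(4)
        state.y[:, 1] = params.v0
        assert np.allclose(nm.coupling_inputs(state, net, params), 15.0 * 2.5)

    @pytest.mark.parametrize("N", [2, 3, 5, 8])
    def test_identical_states_independent_of_size(self, params, N):
        net = nm.NetworkConfig.homogeneous(N, 12.0, 75.0)
        state = NetworkState.zeros(N)
        state.y[:, 1] = 3.0
        expected = 12.0 * nm.sigmoid(3.0, params)
        assert np.allclose(nm.coupling_inputs(state, net, params), expected)

    def test_two_column_directed_entry(self, params):
        K = np.zeros((2, 2))
        K[1, 0] = 10.0  # column 2 -> column 1
        net = nm.NetworkConfig(N=2, K=K, p_const=75.0)
        state = NetworkState.zeros(2)  # both at y1 - y2 = 0
        coup = nm.coupling_inputs(state, net, params)
        assert coup[0] == pytest.approx(10.0 * nm.sigmoid(0.0, params), rel=1e-12)
        assert coup[0] == pytest.approx(1.678, abs=2e-3)
        assert coup[1] == 0.0

    def test_size_mismatch_rejected(self, params):
        net = nm.NetworkConfig.homogeneous(3, 1.0, 75.0)
        with pytest.raises(ValueError):
            nm.coupling_inputs(NetworkState.zeros(4), net, params)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        N = 5
        net = nm.NetworkConfig.homogeneous(N, 9.0, 75.0)
        state = NetworkState.zeros(N)
        state.y[:] = rng.normal(0, 5, (N, 3))
        perm = rng.permutation(N)
        permuted = NetworkState(state.y[perm], state.z[perm], state.xi[perm])
        assert np.allclose(
            nm.coupling_inputs(state, net)[perm], nm.coupling_inputs(permuted, net)
        )


class TestTotalInputAndObservable:
    def test_reduces_to_constant(self):
        net = nm.NetworkConfig(N=2, K=np.zeros((2, 2)), p_const=80.0)
        state = NetworkState.zeros(2)
        assert nm.total_pyramidal_input(0.0, 0, state, net) == pytest.approx(80.0)

    def test_sine_contributes_nothing_at_t_zero(self):
        net = nm.NetworkConfig.single_column(90.0)
        drive = nm.DriveSpec(mode="sine", amplitude=45.0, frequency=0.25)
        assert nm.total_pyramidal_input(0.0, 0, NetworkState.zeros(1), net, drive) == pytest.approx(90.0)

    def test_component_sum(self, params):
        # constant + coupling + drive + noise add linearly
        net = nm.NetworkConfig.homogeneous(2, 5.0, 75.0)
        state = NetworkState.zeros(2)
        state.xi[:] = -3.1
        drive = nm.DriveSpec(mode="sine", amplitude=45.0, frequency=0.25)
        t = 1.0  # sin(pi/2) = 1
        coup = nm.coupling_inputs(state, net, params)[0]
        expected = 75.0 + coup + 45.0 - 3.1
        assert nm.total_pyramidal_input(t, 0, state, net, drive, params) == pytest.approx(expected)

    def test_eeg_average(self):
        state = NetworkState.zeros(4)
        state.y[:, 1] = [1.0, 2.0, 3.0, 4.0]
        per, avg = nm.eeg_observable(state)
        assert np.allclose(per, [1, 2, 3, 4])
        assert avg == pytest.approx(2.5)
        sym = NetworkState.zeros(2)
        sym.y[:, 1] = [3.0, -3.0]
        assert nm.eeg_observable(sym)[1] == pytest.approx(0.0)
        single = NetworkState.zeros(1)
        single.y[0, 1] = 1.25
        assert nm.eeg_observable(single)[1] == pytest.approx(1.25)


class TestParameterValidation:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            nm.ColumnParameters(A=-1.0)

    def test_noncanonical_connectivity_warns(self):
        with pytest.warns(UserWarning):
            nm.ColumnParameters(C3=30.0, C4=35.0)

    def test_network_invariants(self):
        with pytest.raises(ValueError):
            nm.NetworkConfig(N=2, K=np.eye(2), p_const=75.0)  # self-connectivity
        with pytest.raises(ValueError):
            nm.NetworkConfig(N=2, K=-np.ones((2, 2)) + np.eye(2), p_const=75.0)
        with pytest.raises(ValueError):
            nm.NetworkConfig(N=2, K=np.zeros((2, 2)), p_const=-1.0)
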