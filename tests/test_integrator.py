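"""Tests of the stochastic Heun integrator and the run manager."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import neuromass as nm
from neuromass.drive import OUConfig
from neuromass.model import NetworkState, sigmoid
from neuromass.simulate import SimulationConfig


def _reference_rhs(p_exc, P):
    """Right-hand side for the high-order reference integration oracle."""

    def rhs(t, s):
        y0, y1, y2, z0, z1, z2 = s
        return [
            z0, z1, z2,
            P.A * P.a * sigmoid(y1 - y2, P) - 2 * P.a * z0 - P.a**2 * y0,
            P.A * P.a * (p_exc + P.C2 * sigmoid(P.C1 * y0, P)) - 2 * P.a * z1 - P.a**2 * y1,
            P.B * P.b * P.C4 * sigmoid(P.C3 * y0, P) - 2 * P.b * z2 - P.b**2 * y2,
        ]

    return rhs


def _single_column_run(p_exc, h, duration, initial=None):
    net = nm.NetworkConfig.single_column(p_exc)
    sim = SimulationConfig(h=h, duration=duration, transient=0.0, seed=0)
    return nm.simulate(net, None, OUConfig(D=0.0), None, sim, initial_state=initial)


class TestHeunStep:
    def test_scalar_linear_decay(self):
        # Heun on dx/dt = -x with h = 0.1: x1 = 1 - 0.1 + 0.005
        assert nm.ou_step(1.0, OUConfig(0.0, 1.0), 0.1, 0.0) == pytest.approx(0.905, rel=1e-14)

    def test_fixed_point_is_stationary(self, params):
        eq = nm.fixed_points(90.0, params)[0]
        state = NetworkState(
            y=eq.state.as_array()[:3][None, :].copy(),
            z=np.zeros((1, 3)),
            xi=np.zeros(1),
        )
        net = nm.NetworkConfig.single_column(90.0)
        out = nm.heun_step(state, 0.0, 0.001, params, net, OUConfig(D=0.0), None, np.zeros(1))
        assert np.allclose(out.y, state.y, atol=1e-12)
        assert np.allclose(out.z, state.z, atol=1e-9)

    def test_python_step_matches_compiled_kernel(self, params):
        # 100 stochastic steps of the coupled network, replayed step by step
        net = nm.NetworkConfig.homogeneous(4, 15.0, 75.0)
        ou = OUConfig()
        sim = SimulationConfig(h=0.001, duration=0.1, transient=0.0, seed=5)
        ts = nm.simulate(net, params, ou, None, sim)
        gens = [np.random.default_rng(c) for c in np.random.SeedSequence(5).spawn(4)]
        xi0 = np.array([g.normal(0.0, nm.ou_stationary_std(ou)) for g in gens])
        state = NetworkState(np.zeros((4, 3)), np.zeros((4, 3)), xi0)
        W = np.column_stack([g.standard_normal(100) for g in gens])
        for k in range(100):
            state = nm.heun_step(state, k * 0.001, 0.001, params, net, ou, None, W[k])
        assert np.max(np.abs(state.y[:, 1] - state.y[:, 2] - ts.eeg[-1])) < 1e-10


class TestDeterministicAccuracy:
    def test_matches_reference_integrator(self, params):
        # fixed 100 Hz input from rest: compare y1 - y2 at t = 5 s against
        # an 8th-order adaptive reference
        ref = solve_ivp(
            _reference_rhs(100.0, params), (0, 5), np.zeros(6),
            method="DOP853", rtol=1e-11, atol=1e-12,
        )
        yref = ref.y[1, -1] - ref.y[2, -1]
        ts = _single_column_run(100.0, 0.001, 5.0)
        assert ts.eeg[-1, 0] == pytest.approx(yref, abs=1e-3)

    def test_second_order_convergence_on_limit_cycle(self, params):
        # start inside the alpha basin so the trajectory is genuinely dynamic
        eq = nm.fixed_points(100.0, params)[-1]
        s0 = eq.state.as_array()
        s0[1] += 1.0
        ref = solve_ivp(
            _reference_rhs(100.0, params), (0, 0.5), s0,
            method="DOP853", rtol=1e-12, atol=1e-13,
        )
        yref = ref.y[1, -1] - ref.y[2, -1]
        errs = []
        for h in (0.002, 0.001, 0.0005):
            init = NetworkState(s0[:3][None, :].copy(), s0[3:][None, :].copy(), np.zeros(1))
            ts = _single_column_run(100.0, h, 0.5, initial=init)
            errs.append(abs(ts.eeg[-1, 0] - yref))
        # halving h should cut the global error by ~4 (second order)
        assert 2.5 < errs[0] / errs[1] < 6.0
        assert 2.5 < errs[1] / errs[2] < 6.0


class TestSimulate:
    def test_settles_to_equilibrium_below_hopf(self, params):
        ts = _single_column_run(80.0, 0.001, 50.0)
        final = ts.final_state.column(0)
        d = nm.column_derivatives(final, 80.0, params).as_array()
        assert np.max(np.abs(d)) < 1e-6

    def test_alpha_limit_cycle_above_hopf(self, params):
        # inside the bistable window the alpha cycle surrounds the upper
        # (unstable-focus) equilibrium; start from its basin
        eq = nm.fixed_points(100.0, params)[-1]
        s0 = eq.state.as_array()
        s0[1] += 1.0
        init = NetworkState(s0[:3][None, :].copy(), s0[3:][None, :].copy(), np.zeros(1))
        ts = _single_column_run(100.0, 0.001, 50.0, initial=init)
        label = nm.classify_attractor(ts.eeg[10_000:, 0], ts.fs)
        assert label.label == "alpha_cycle"
        assert 8.0 <= label.dominant_frequency_hz <= 13.0

    def test_same_seed_bit_identical(self):
        net = nm.NetworkConfig.homogeneous(4, 15.0, 75.0)
        sim = SimulationConfig(h=0.001, duration=2.0, transient=0.0, seed=9)
        a = nm.simulate(net, sim=sim)
        b = nm.simulate(net, sim=sim)
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.xi, b.xi)

    def test_shared_noise_keeps_columns_identical(self):
        net = nm.NetworkConfig.homogeneous(4, 15.0, 75.0)
        sim = SimulationConfig(h=0.001, duration=5.0, transient=0.0, seed=3, share_noise=True)
        ts = nm.simulate(net, sim=sim)
        for i in range(1, 4):
            assert np.array_equal(ts.eeg[:, 0], ts.eeg[:, i])

    def test_blowup_reports_column_and_time(self):
        with pytest.raises(nm.NumericalBlowupError, match="column 0"):
            _single_column_run(90.0, 1.0, 100.0)  # absurd 1 s step

    def test_record_stride_downsamples(self):
        net = nm.NetworkConfig.single_column(90.0)
        full = nm.simulate(net, None, OUConfig(D=0.0), None,
                           SimulationConfig(h=0.001, duration=1.0, transient=0.0))
        dec = nm.simulate(net, None, OUConfig(D=0.0), None,
                          SimulationConfig(h=0.001, duration=1.0, transient=0.0, record_stride=10))
        assert dec.fs == pytest.approx(100.0)
        assert np.allclose(dec.eeg[:, 0], full.eeg[::10, 0])


class TestTransientAndIO:
    @staticmethod
    def _series(duration_s=11.0, fs=10.0):
        n = int(duration_s * fs) + 1
        rng = np.random.default_rng(0)
        return nm.TimeSeries(fs=fs, t0=0.0, eeg=rng.normal(size=(n, 2)))

    def test_zero_cut_is_identity(self):
        ts = self._series()
        assert nm.discard_transient(ts, 0.0) is ts

    def test_cut_lengths(self):
        ts = self._series(duration_s=11.0, fs=10.0)
        cut = nm.discard_transient(ts, 1.0)
        assert cut.t[0] == pytest.approx(1.0)
        assert cut.duration == pytest.approx(ts.duration - 1.0, abs=0.2)

    def test_cut_between_samples_keeps_next(self):
        ts = self._series(fs=10.0)
        cut = nm.discard_transient(ts, 0.55)
        assert cut.t[0] == pytest.approx(0.6)

    def test_cut_beyond_end_rejected(self):
        with pytest.raises(ValueError):
            nm.discard_transient(self._series(), 100.0)

    def test_save_load_round_trip(self, tmp_path):
        net = nm.NetworkConfig.homogeneous(2, 15.0, 75.0)
        ts = nm.simulate(net, sim=SimulationConfig(h=0.001, duration=0.5, transient=0.0, seed=2))
        path = tmp_path / "run.txt"
        nm.save_timeseries(ts, path)
        back = nm.load_timeseries(path)
        assert back.fs == ts.fs
        assert np.array_equal(back.eeg, ts.eeg)
        assert back.provenance["network"]["p_const"] == 75.0
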