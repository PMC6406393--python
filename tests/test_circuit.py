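"""Circuit model: Hill kinetics, derivatives, integration, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import root

from page4.circuit import (CircuitError, CircuitParams, CircuitState,
                           hill_inhibition, derivatives, simulate, _rhs)
from page4.calibrate import (CalibrationError, calibrate_default_params,
                             measured_period)
from page4.oscillation import detect_period
from page4.protocols import constant_adt

from conftest import rk4_integrate


class TestHillInhibition:
    @pytest.mark.parametrize("x, x0, n, expected", [
        (0.0, 1.0, 4, 1.0),            # no repressor -> full production
        (1.0, 1.0, 4, 0.5),            # half-saturation at the threshold
        (1.0, 1.0, 9, 0.5),            # ... for any coefficient
        (2.0, 1.0, 4, 1.0 / 17.0),     # direct arithmetic
    ])
    def test_values(self, x, x0, n, expected):
        assert hill_inhibition(x, x0, n) == pytest.approx(expected, abs=1e-15)

    def test_invalid_parameters(self):
        with pytest.raises(CircuitError):
            hill_inhibition(1.0, 0.0, 4)
        with pytest.raises(CircuitError):
            hill_inhibition(1.0, 1.0, 0.5)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert hill_inhibition(hi, 2.0, 4) <= hill_inhibition(lo, 2.0, 4) + 1e-15


class TestDerivatives:
    def test_matches_rate_equations(self, params):
        state = CircuitState(W=0.9, H=0.4, C=0.3, K=0.2, A=0.6)
        d = derivatives(state, 0.0, params)
        p = params
        assert d.W == pytest.approx(p.g_W - (p.k_H + p.delta_W) * 0.9)
        assert d.H == pytest.approx(p.k_H * 0.9 - p.k_C * 0.2 * 0.4
                                    - p.delta_H * 0.4)
        assert d.C == pytest.approx(p.k_C * 0.2 * 0.4 - p.delta_C * 0.3)
        assert d.K == pytest.approx(p.g_K * hill_inhibition(0.6, p.A0, p.n_A)
                                    - p.delta_K * 0.2)
        assert d.A == pytest.approx(p.g_A * hill_inhibition(0.4, p.H0, p.n_H)
                                    - p.delta_A * 0.6)

    def test_full_adt_suppresses_ar_production(self, params):
        state = CircuitState(W=1.0, H=0.1, C=0.1, K=0.1, A=0.7)
        d = derivatives(state, 10.0, params, constant_adt(t_on=0.0, u=1.0))
        assert d.A == pytest.approx(-params.delta_A * 0.7)

    def test_negative_state_rejected(self, params):
        with pytest.raises(CircuitError):
            derivatives(CircuitState(1, -0.1, 0, 0, 0), 0.0, params)

    def test_fixed_point_flux_balance(self, params):
        """At a steady state, WT production balances total PAGE4 loss."""
        sol = root(lambda y: _rhs(0.0, y, params, 0.0, 0.0),
                   np.array([1.0, 0.3, 0.4, 0.5, 0.3]), tol=1e-12)
        assert sol.success
        W, H, C, K, A = sol.x
        residual = np.abs(_rhs(0.0, sol.x, params, 0.0, 0.0))
        assert np.max(residual) < 1e-8
        # summing the W, H, C equations at steady state:
        assert params.g_W == pytest.approx(
            params.delta_W * W + params.delta_H * H + params.delta_C * C,
            rel=1e-8)


class TestSimulate:
    def test_isolated_wt_decay_half_life(self, params):
        """With conversion and production switched off, W halves in 150 h."""
        p = params.replace(g_W=1e-30, k_H=1e-30)
        traj = simulate(p, None, CircuitState(1, 0, 0, 0, 0), (0.0, 200.0),
                        output_dt=0.5)
        w150 = traj.species("W")[np.searchsorted(traj.times, 150.0)]
        assert w150 == pytest.approx(0.5, rel=1e-6)

    def test_sustained_oscillation_amplitude(self, params, on_cycle_ic):
        traj = simulate(params, None, on_cycle_ic, (0.0, 2000.0))
        h = traj.species("H")[traj.times >= 1000.0]
        assert np.ptp(h) > 0.10 * h.mean()

    def test_zero_production_everything_decays(self, params):
        """Without sources, total PAGE4 mass and the kinase/AR levels
        decay monotonically toward zero (conversions only shuffle mass
        between the phospho-forms)."""
        p = params.replace(g_W=1e-30, g_A=1e-30, g_K=1e-30, beta_OE=0.0)
        traj = simulate(p, None, CircuitState(1, 1, 1, 1, 1), (0.0, 2000.0))
        total_page4 = traj.states[:, :3].sum(axis=1)   # W + H + C
        assert np.all(np.diff(total_page4) <= 1e-12)
        for s in ("W", "K", "A"):
            assert np.all(np.diff(traj.species(s)) <= 1e-12)
        assert np.all(traj.states[-1] < 0.05)

    @given(st.tuples(*[st.floats(0.0, 2.0) for _ in range(5)]))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_non_negativity(self, params, y0):
        traj = simulate(params, None, CircuitState(*y0), (0.0, 300.0),
                        output_dt=2.0)
        assert np.all(traj.states >= -1e-9)

    def test_adaptive_matches_rk4_oracle(self, params, on_cycle_ic):
        """Adaptive integration agrees with fixed-step RK4 at dt = 0.01 h."""
        t_end, dt = 2000.0, 0.01
        traj = simulate(params, None, on_cycle_ic, (0.0, t_end), output_dt=0.5)
        grid = np.arange(0.0, t_end + dt / 2, dt)
        oracle = rk4_integrate(
            lambda t, y: _rhs(t, y, params, 0.0, 0.0),
            on_cycle_ic.as_array(), grid)
        sub = oracle[::50]          # every 0.5 h
        scale = np.max(np.abs(sub), axis=0)
        err = np.max(np.abs(traj.states - sub), axis=0) / scale
        assert np.all(err < 1e-4)

    def test_feedback_ablation_kills_oscillation(self, params, cycle,
                                                 on_cycle_ic):
        """Clamping CLK2 opens the loop; the oscillation must die."""
        k_const = cycle.centroid["K"]
        traj = simulate(params, None, on_cycle_ic, (0.0, 6000.0),
                        output_dt=1.0, clamp_K=k_const)
        h = traj.species("H")[traj.times >= 5000.0]
        assert np.ptp(h) < 0.01 * h.mean()

    def test_mean_ar_activity_monotone_in_adt_strength(self, params,
                                                       on_cycle_ic):
        means = []
        for u in (0.0, 0.25, 0.5, 0.75, 1.0):
            traj = simulate(params, constant_adt(t_on=0.0, u=u), on_cycle_ic,
                            (0.0, 3000.0), output_dt=2.0)
            means.append(traj.species("A")[traj.times >= 2000.0].mean())
        assert np.all(np.diff(means) <= 1e-9)

    def test_invalid_spans_rejected(self, params, on_cycle_ic):
        with pytest.raises(CircuitError):
            simulate(params, None, on_cycle_ic, (10.0, 10.0))
        with pytest.raises(CircuitError):
            simulate(params, None, on_cycle_ic, (0.0, 10.0), output_dt=0.0)


class TestCalibration:
    def test_default_half_life_anchor_exact(self, params):
        assert params.delta_W == pytest.approx(math.log(2) / 150.0, rel=1e-12)

    def test_default_period_within_band(self, params):
        period = measured_period(params)
        assert period is not None
        assert 0.9 * 168.0 <= period <= 1.1 * 168.0

    def test_search_finds_band_on_reduced_grid(self):
        p = calibrate_default_params(
            grid={"delta_AK": (0.02,), "k_C": (0.05,), "H0": (0.4,)})
        period = measured_period(p)
        assert period is not None and abs(period - 168.0) <= 0.1 * 168.0

    def test_disabled_period_anchor_returns_template(self):
        p = calibrate_default_params(anchors={"target_period": math.inf})
        assert isinstance(p, CircuitParams)
        assert p.delta_W == pytest.approx(math.log(2) / 150.0)

    def test_no_candidate_raises(self):
        # a grid far too fast for a week-scale cycle
        with pytest.raises(CalibrationError):
            calibrate_default_params(
                grid={"delta_AK": (5.0,), "k_C": (5.0,), "H0": (0.4,)})
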