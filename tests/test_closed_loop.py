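"""Closed-loop simulation, metrics and robustness sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest

from kpcontrol import (PerturbationSpec, scenario_preset, simulate,
                       eradication_time, settling_time, uncertainty_sweep)
from kpcontrol.closed_loop import (eradication_time_channel,
                                   settling_time_channel)
from kpcontrol.integrators import Trajectory


class TestSimulate:
    def test_z_channel_matches_closed_form(self, nominal_result):
        """Exact cancellation makes IL-2 decay as z0 * exp(-k3 t)."""
        traj = nominal_result.trajectory
        k3 = nominal_result.scenario.gains.k3
        exact = 7000.0 * np.exp(-k3 * traj.times)
        assert np.max(np.abs(traj.channel("z") - exact)) < 1e-6

    def test_steady_state_reaches_costate_limit(self, nominal_result):
        """x -> (g2/a)(r2 + k1) = 27000 and the tumour is eradicated."""
        m = nominal_result.metrics
        assert m.steady_state_x == pytest.approx(27000.0, rel=1e-3)
        y = nominal_result.trajectory.channel("y")
        assert y[-1] < 1.0
        assert m.tumour_eradication_time is not None

    def test_determinism(self):
        sc = replace(scenario_preset("fast"), horizon=5.0)
        a, b = simulate(sc), simulate(sc)
        assert np.array_equal(a.trajectory.states, b.trajectory.states)
        assert a.metrics == b.metrics

    def test_diagnostics_channels_populated(self, fast_result):
        traj = fast_result.trajectory
        for name in ("e", "xstar", "V", "Vdot"):
            assert len(traj.diagnostics[name]) == len(traj)
        assert traj.inputs.shape == (len(traj), 2)
        # e = alpha*x - x* by definition
        g = fast_result.scenario.gains
        np.testing.assert_allclose(
            traj.diagnostics["e"],
            g.alpha * traj.channel("x") - traj.diagnostics["xstar"])

    def test_zero_order_hold_converges_to_continuous(self):
        base = replace(scenario_preset("fast"), horizon=20.0)
        cont = simulate(base)
        zoh = simulate(replace(base, measurement_interval=0.01))
        y_c = cont.trajectory.channel("y")
        y_d = zoh.trajectory.channel("y")
        assert np.max(np.abs(y_c - y_d)) / np.max(np.abs(y_c)) < 0.01

    def test_zero_order_hold_inputs_piecewise_constant(self):
        # sampling must stay well inside the sampled-data stability
        # region: the open-loop IL-2 channel grows at ~p2*x/g3 per day,
        # so intervals beyond a few hundredths of a day destabilise it
        base = replace(scenario_preset("fast"), horizon=5.0)
        coarse = simulate(replace(base, measurement_interval=0.02))
        fine = simulate(replace(base, measurement_interval=0.01))
        u_coarse = coarse.trajectory.channel("u1")
        i = np.searchsorted(coarse.trajectory.times, 0.01)
        assert u_coarse[i] == u_coarse[0]          # inside the first hold
        u_fine = fine.trajectory.channel("u1")
        assert u_fine[np.searchsorted(fine.trajectory.times, 0.01)] != u_fine[0]

    def test_fractional_zoh_unsupported(self):
        sc = replace(scenario_preset("fractional"), measurement_interval=0.5)
        with pytest.raises(ValueError, match="hold"):
            simulate(sc)


class TestMetrics:
    def test_eradication_time_closed_forms(self):
        t = np.arange(0.0, 120.0, 0.01)
        y = 12000.0 * np.exp(-0.25 * t)
        assert eradication_time_channel(t, y, 1.0) == \
            pytest.approx(math.log(12000.0) / 0.25, abs=0.01)
        z = 7000.0 * np.exp(-0.25 * t)
        assert eradication_time_channel(t, z, 1.0) == \
            pytest.approx(math.log(7000.0) / 0.25, abs=0.01)

    def test_eradication_never_below_returns_none(self):
        t = np.arange(0.0, 10.0, 0.1)
        assert eradication_time_channel(t, np.full_like(t, 5.0), 1.0) is None

    def test_eradication_requires_sustained_crossing(self):
        t = np.arange(0.0, 10.0, 1.0)
        v = np.array([5.0, 0.5, 3.0, 0.4, 0.3, 0.2, 0.1, 0.1, 0.1, 0.1])
        # dips below at t=1 but rebounds; sustained only from t=3
        assert eradication_time_channel(t, v, 1.0) == 3.0

    def test_settling_time_closed_form(self):
        t = np.arange(0.0, 200.0, 0.01)
        x = 27000.0 * (1.0 - np.exp(-0.1 * t))
        assert settling_time_channel(t, x, 0.02) == \
            pytest.approx(math.log(50.0) / 0.1, abs=0.05)

    def test_settling_constant_channel_is_t0(self):
        t = np.arange(0.0, 10.0, 0.1)
        assert settling_time_channel(t, np.full_like(t, 4.2)) == 0.0

    def test_settling_nonconvergent_raises(self):
        t = np.arange(0.0, 100.0, 0.01)
        with pytest.raises(ValueError, match="not converged"):
            settling_time_channel(t, np.sin(t), 0.02)

    def test_metric_accessors_on_result(self, fast_result):
        assert eradication_time(fast_result, "y") == \
            fast_result.metrics.tumour_eradication_time
        assert settling_time(fast_result, "x") == \
            fast_result.metrics.effector_settling_time
        with pytest.raises(KeyError):
            eradication_time(fast_result, "w")


class TestSweep:
    def test_zero_level_is_identical_to_base(self):
        base = replace(scenario_preset("fast"), horizon=10.0)
        ref = simulate(base)
        swept = uncertainty_sweep(base, [0.0])[0]
        assert np.array_equal(swept.trajectory.states, ref.trajectory.states)

    def test_controller_keeps_nominal_belief(self):
        base = replace(scenario_preset("fast"), horizon=10.0)
        res = uncertainty_sweep(base, [0.5])[0]
        assert res.scenario.true_params != base.true_params
        assert res.scenario.controller_params == base.true_params

    def test_random_sign_is_seeded(self):
        base = replace(scenario_preset("fast"), horizon=5.0)
        spec = PerturbationSpec(direction="random_sign")
        a = uncertainty_sweep(base, [0.3], spec)[0]
        b = uncertainty_sweep(base, [0.3], spec)[0]
        assert a.scenario.true_params == b.scenario.true_params

    def test_deflate_direction(self):
        base = replace(scenario_preset("fast"), horizon=5.0)
        spec = PerturbationSpec(direction="deflate", affected=("r2",))
        res = uncertainty_sweep(base, [0.5], spec)[0]
        assert res.scenario.true_params.r2 == pytest.approx(0.09)

    def test_divergent_level_is_collected_not_raised(self):
        # perturbing the exactly-cancelled IL-2 production term leaves a
        # residual ~ 0.1 * 200 * z >> k3 * z: guaranteed blow-up
        base = replace(scenario_preset("fast"), horizon=60.0)
        spec = PerturbationSpec(direction="inflate", affected=("p2",))
        results = uncertainty_sweep(base, [0.0, 0.1], spec)
        assert not results[0].metrics.diverged
        assert results[1].metrics.diverged
        assert results[1].metrics.divergence_time is not None
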