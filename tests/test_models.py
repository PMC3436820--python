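"""Model definitions, parameter bookkeeping and trajectory simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from odeinput.models import (GaussianInput, IntegrationError, ParameterSet,
                             Trajectory, jakstat_model, model_from_config,
                             simulate, toy_model)
from odeinput.splines import interpolating_spline
from odeinput.synthetic import StudyDesign, true_parameter_set


K_TRUE = np.array([0.01, 1.0, 0.5, 0.1])


class TestToyRhs:
    def test_hand_evaluated_back_reaction(self):
        # u = 0 silences the catalyzed forward flux; X1 gains only km1*x2
        model = toy_model()
        dx = model.rhs(0.0, np.array([30.0, 20.0, 50.0]), np.array([0.0]), K_TRUE, None)
        assert dx[0] == pytest.approx(20.0)
        assert dx.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_rates_zero_derivative(self, rng):
        model = toy_model()
        x = rng.uniform(0, 100, 3)
        dx = model.rhs(0.0, x, np.array([50.0]), np.zeros(4), None)
        np.testing.assert_array_equal(dx, np.zeros(3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_closed_chain_conserves_mass(self, seed):
        rng = np.random.default_rng(seed)
        model = toy_model()
        dx = model.rhs(0.0, rng.uniform(0, 100, 3), rng.uniform(0, 100, 1),
                       rng.uniform(0, 2, 4), None)
        assert dx.sum() == pytest.approx(0.0, abs=1e-10)


class TestToySimulation:
    def test_constant_when_all_fluxes_off(self):
        ps = ParameterSet.create(
            names={"dynamic": ["k1", "km1", "k2", "km2"], "scaling_offset": [],
                   "initial": ["a", "b", "c"], "input_control": []},
            values={"dynamic": [0.5, 1e-30, 1e-30, 1e-30], "initial": [30.0, 20.0, 50.0]})
        ps.dynamic[1:] = -300.0  # log10 scale: effectively zero rates
        with pytest.warns(RuntimeWarning, match="positivity floor"):
            # u = 0 pushes the input observable through the log10 floor
            traj = simulate(toy_model(), ps, lambda t: 0.0, np.linspace(0, 50, 6),
                            backend="generic")
        np.testing.assert_allclose(traj.states, np.tile([30, 20, 50], (6, 1)), rtol=1e-9)

    def test_total_mass_stays_at_100(self, design):
        traj = simulate(toy_model(), true_parameter_set(design), design.input,
                        design.times)
        np.testing.assert_allclose(traj.states.sum(axis=1), 100.0, rtol=1e-7)

    def test_self_convergence_under_tolerance_halving(self, design):
        ps = true_parameter_set(design)
        t = design.times
        a = simulate(toy_model(), ps, design.input, t, rtol=1e-8, atol=1e-10)
        b = simulate(toy_model(), ps, design.input, t, rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(a.states - b.states)) < 10 * 1e-8 * 100

    def test_bitwise_deterministic(self, design):
        ps = true_parameter_set(design)
        a = simulate(toy_model(), ps, design.input, design.times)
        b = simulate(toy_model(), ps, design.input, design.times)
        np.testing.assert_array_equal(a.states, b.states)

    @pytest.mark.parametrize("input_kind", ["gaussian", "spline"])
    def test_fast_path_agrees_with_generic(self, design, input_kind):
        ps = true_parameter_set(design)
        if input_kind == "gaussian":
            fn = design.input
        else:
            t = design.times
            fn = interpolating_spline(t, np.log10(design.input(t)), log_scale=True)
        fast = simulate(toy_model(), ps, fn, design.times, backend="fast")
        gen = simulate(toy_model(), ps, fn, design.times, backend="generic")
        np.testing.assert_allclose(fast.states, gen.states, rtol=1e-6, atol=1e-7)
        np.testing.assert_allclose(fast.observables, gen.observables, rtol=1e-6)


def _jakstat_ps(k=(1.95, 0.11, 2.0, 1.0), s=(1.0, 1.0, 1.0)):
    ps = ParameterSet.create(
        names={"dynamic": ["k1", "k2", "k3", "k4"],
               "scaling_offset": ["s1", "s2", "s3"],
               "initial": ["x1", "x2", "x3", "x4"], "input_control": []},
        values={"dynamic": list(k), "scaling_offset": list(s),
                "initial": [1.0, 1.0, 1.0, 1.0]},
        log10={"dynamic": [True] * 4, "scaling_offset": [True] * 3,
               "initial": [False] * 4})
    ps.initial[:] = [1.0, 0.0, 0.0, 0.0]
    return ps


class TestJakStat:
    def test_rest_state_without_input_is_steady(self):
        model = jakstat_model(tau=1.0)
        dx = model.rhs(0.0, np.array([1.0, 0, 0, 0]), np.array([0.0]),
                       np.array([1.95, 0.11, 2.0, 1.0]), lambda j: 0.0)
        np.testing.assert_array_equal(dx, np.zeros(4))

    def test_observation_sums(self):
        # monomer bookkeeping: each cytoplasmic dimer contributes two
        # STAT5 molecules, so y1 = x2 + 2*x3 and y2 = x1 + x2 + 2*x3
        model = jakstat_model()
        y = model.observation(np.array([0.4, 0.2, 0.1, 0.3]), np.array([2.0]),
                              np.array([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(y, [0.4, 0.8, 2.0])

    def test_total_stat5_conserved_through_delay_chain(self):
        model = jakstat_model(tau=1.0)
        times = np.linspace(0, 60, 20)
        u = np.clip((times / 10.0) ** 2 * np.exp(2 * (1 - times / 10.0)), 1e-3, None)
        spl = interpolating_spline(times, np.log10(u), log_scale=True)
        traj = simulate(model, _jakstat_ps(), spl, times)
        total = traj.states @ np.array([1.0, 1.0, 2.0, 2.0])
        np.testing.assert_allclose(total, 1.0, rtol=1e-7)

    def test_tau_zero_reduces_to_plain_ode(self):
        model = jakstat_model(tau=0.0)
        times = np.linspace(0, 60, 16)
        u_fn = GaussianInput(1.0, 10.0, 8.0)
        traj = simulate(model, _jakstat_ps(), u_fn, times, backend="generic")

        def plain(t, x, k=(1.95, 0.11, 2.0, 1.0)):
            u = u_fn(t)
            v1, v2, v3, v4 = k[0] * u * x[0], k[1] * x[1] ** 2, k[2] * x[2], k[3] * x[3]
            return [-v1 + 2 * v4, v1 - 2 * v2, v2 - v3, v3 - v4]

        sol = solve_ivp(plain, (0, 60), [1.0, 0, 0, 0], t_eval=times,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(traj.states, sol.y.T, rtol=1e-6, atol=1e-9)

    def test_chain_converges_to_direct_history_solution(self):
        # fixed-step RK4 method-of-steps with linear history interpolation
        # as the independent delay-equation oracle
        tau, k = 1.0, (1.95, 0.11, 2.0, 1.0)
        u_fn = GaussianInput(1.0, 10.0, 8.0)
        t_end, dt = 30.0, 0.002
        n = int(t_end / dt)
        ts = np.arange(n + 1) * dt
        x = np.zeros((n + 1, 4))
        x[0] = [1.0, 0, 0, 0]
        hist = x[:, 3]

        def x4_delayed(t):
            td = t - tau
            if td <= 0:
                return 0.0
            j = min(int(td / dt), n - 1)
            w = (td - ts[j]) / dt
            return (1 - w) * hist[j] + w * hist[j + 1]

        def f(t, xi):
            u = u_fn(t)
            v1, v2, v3 = k[0] * u * xi[0], k[1] * xi[1] ** 2, k[2] * xi[2]
            v4 = k[3] * x4_delayed(t)
            return np.array([-v1 + 2 * v4, v1 - 2 * v2, v2 - v3, v3 - v4])

        for i in range(n):
            t = ts[i]
            k1 = f(t, x[i])
            k2 = f(t + dt / 2, x[i] + dt / 2 * k1)
            k3 = f(t + dt / 2, x[i] + dt / 2 * k2)
            k4 = f(t + dt, x[i] + dt * k3)
            x[i + 1] = x[i] + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        check = np.linspace(0, 30, 7)
        oracle = np.stack([x[int(round(t / dt))] for t in check])
        errs = []
        for n_chain in (4, 16, 64):
            traj = simulate(jakstat_model(tau=tau), _jakstat_ps(k), u_fn, check,
                            n_chain=n_chain, backend="generic")
            errs.append(np.max(np.abs(traj.states - oracle)))
        assert errs[2] < errs[0]  # refinement helps
        assert errs[2] < 5e-3     # and lands near the true delay solution


class TestParameterSet:
    def test_log10_storage_and_natural_roundtrip(self):
        ps = true_parameter_set()
        np.testing.assert_allclose(ps.dynamic, np.log10(K_TRUE))
        np.testing.assert_allclose(ps.natural("dynamic"), K_TRUE)

    def test_free_vector_block_order_and_with_free(self):
        ps = ParameterSet.create(
            names={"dynamic": ["k"], "scaling_offset": ["s"],
                   "initial": ["x0"], "input_control": ["v1"]},
            values={"dynamic": [2.0], "scaling_offset": [3.0],
                    "initial": [4.0], "input_control": [0.5]},
            fixed={"scaling_offset": [True]})
        assert ps.free_names == ["k", "x0", "v1"]
        ps2 = ps.with_free(np.array([1.0, 2.0, 3.0]))
        assert ps2.dynamic[0] == 1.0 and ps2.input_control[0] == 3.0
        assert ps2.scaling_offset[0] == ps.scaling_offset[0]  # fixed untouched

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ParameterSet.create(
                names={"dynamic": ["k"], "scaling_offset": [],
                       "initial": ["k"], "input_control": []},
                values={"dynamic": [1.0], "initial": [1.0]})

    def test_nonpositive_log_value_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ParameterSet.create(
                names={"dynamic": ["k"], "scaling_offset": [],
                       "initial": [], "input_control": []},
                values={"dynamic": [-1.0]})


TOY_CONFIG = {
    "name": "toy_from_config",
    "states": ["X1", "X2", "X3"],
    "inputs": ["u"],
    "dynamic": ["k1", "km1", "k2", "km2"],
    "odes": [
        "-k1*u*X1 + km1*X2",
        "k1*u*X1 - km1*X2 - k2*X2 + km2*X3",
        "k2*X2 - km2*X3",
    ],
    "observables": {"z1": "X1", "z2": "X2", "z3": "X3"},
    "initial": [30.0, 20.0, 50.0],
}


class TestConfigModels:
    def test_config_toy_matches_builtin_dynamics(self, design):
        model = model_from_config(TOY_CONFIG)
        ps = ParameterSet.create(
            names={"dynamic": list(model.dynamic_names), "scaling_offset": [],
                   "initial": ["a", "b", "c"], "input_control": []},
            values={"dynamic": K_TRUE, "initial": [30.0, 20.0, 50.0]})
        traj = simulate(model, ps, design.input, design.times, backend="generic")
        ref = simulate(toy_model(), true_parameter_set(design), design.input,
                       design.times, backend="generic")
        np.testing.assert_allclose(traj.states, ref.states, rtol=1e-8)

    def test_negative_state_flagged(self):
        cfg = {"name": "drain", "states": ["A"], "inputs": [], "dynamic": ["r"],
               "odes": ["-r"], "observables": {"yA": "A"}, "initial": [1.0]}
        model = model_from_config(cfg)
        ps = ParameterSet.create(
            names={"dynamic": ["r"], "scaling_offset": [], "initial": ["A0"],
                   "input_control": []},
            values={"dynamic": [1.0], "initial": [1.0]})
        with pytest.raises(IntegrationError, match="negative state"):
            simulate(model, ps, lambda t: np.zeros(0), np.linspace(0, 10, 5),
                     backend="generic")


def test_trajectory_validates_shapes():
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(np.array([0.0, 0.0]), np.zeros((2, 1)), np.zeros((2, 1)),
                   np.zeros((2, 1)))
    with pytest.raises(ValueError, match="row count"):
        Trajectory(np.array([0.0, 1.0]), np.zeros((3, 1)), np.zeros((2, 1)),
                   np.zeros((2, 1)))
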