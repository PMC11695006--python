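"""RK4 integration: tableau, grids, constraints, oracles, determinism."""

import copy
import math

import numpy as np
import pytest

from mospec.expressions import evaluate, parse_expression
from mospec.model import ConstraintDef, resolve_parameters
from mospec.simulate import (
    ConstraintViolation, TimeGrid, check_constraints, rk4_step, simulate,
)


class TestRk4Step:
    def test_zero_field_leaves_state_unchanged(self):
        y = np.array([1.0, -2.0, 3.0])
        out = rk4_step(lambda t, s: np.zeros_like(s), 0.0, y, 0.1)
        assert np.array_equal(out, y)

    def test_exponential_decay_single_step(self):
        # hand-applied tableau for y' = -y, y=1, h=0.1:
        # k1=-1, k2=-0.95, k3=-0.9525, k4=-0.90475 -> y1 = 0.9048375
        out = rk4_step(lambda t, y: -y, 0.0, np.array([1.0]), 0.1)
        assert out[0] == pytest.approx(0.9048375, abs=1e-12)

    def test_constant_drift_is_exact(self):
        out = rk4_step(lambda t, y: np.ones_like(y), 0.0, np.array([0.0]), 0.5)
        assert out[0] == 0.5

    def test_non_finite_derivative_reports_time(self):
        with pytest.raises(FloatingPointError, match="t=2.5"):
            rk4_step(lambda t, y: np.array([np.inf]), 2.5, np.array([1.0]), 0.1)


class TestTimeGrid:
    def test_exact_multiple(self):
        times = TimeGrid(0.0, 1.0, 0.01).times()
        assert len(times) == 101
        assert times[0] == 0.0 and times[-1] == 1.0

    def test_partial_final_step(self):
        times = TimeGrid(0.0, 1.0, 0.3).times()
        assert np.allclose(times, [0.0, 0.3, 0.6, 0.9, 1.0])
        assert times[-1] == 1.0

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            TimeGrid(0.0, 1.0, -0.1)


class TestCheckConstraints:
    def test_no_constraints(self, two_lovers):
        env = resolve_parameters(two_lovers)
        assert check_constraints(two_lovers, env) == []

    def test_single_violation_reports_code(self, toy):
        env = resolve_parameters(toy)
        env["k"] = -1.0
        assert check_constraints(toy, env) == [101]

    def test_codes_in_declaration_order(self, toy):
        env = resolve_parameters(toy)
        env["k"], env["cap"] = -1.0, 0.0
        assert check_constraints(toy, env) == [101, 102]
        env["k"] = 1.0
        assert check_constraints(toy, env) == [102]


class TestSimulate:
    def test_zero_field_constant_trajectories(self, two_lovers):
        spec = copy.deepcopy(two_lovers)
        for v in spec.state_variables:
            v.defining_expression = "0"
        res = simulate(spec, "Default", TimeGrid(0, 1, 0.1))
        assert np.all(res.state_trajectories["R"] == 1.0)
        assert np.all(res.state_trajectories["J"] == 1.0)

    def test_decoupled_exponential_oracle(self, two_lovers):
        res = simulate(two_lovers, "Decoupled", TimeGrid(0.0, 1.0, 0.01), seed=1)
        assert abs(res.state_trajectories["R"][-1] - math.exp(-1)) < 1e-8
        assert abs(res.state_trajectories["J"][-1] - math.exp(-1)) < 1e-8

    def test_linear_system_matrix_exponential_oracle(self, two_lovers):
        from scipy.linalg import expm

        for config in ("Default", "JulietIndifferent"):
            env = resolve_parameters(two_lovers, config)
            A = np.array([[env["a"], env["b"]], [env["c"], env["d"]]])
            y0 = np.array([env["R0"], env["J0"]])
            expected = expm(A) @ y0
            res = simulate(two_lovers, config, TimeGrid(0.0, 1.0, 0.01))
            got = np.array([res.state_trajectories["R"][-1],
                            res.state_trajectories["J"][-1]])
            assert np.max(np.abs(got - expected)) < 1e-6

    def test_seir_population_is_conserved(self, seir):
        res = simulate(seir, "Default", TimeGrid(0.0, 40.0, 0.05))
        total = sum(res.state_trajectories[n] for n in "SEIR")
        assert np.max(np.abs(total - 1000.0)) / 1000.0 < 1e-9

    def test_fourth_order_convergence(self, two_lovers):
        # y' = -y via the Decoupled configuration; halving the step must
        # shrink the terminal error by ~2^4
        errs = []
        for step in (0.1, 0.05):
            res = simulate(two_lovers, "Decoupled", TimeGrid(0.0, 1.0, step))
            errs.append(abs(res.state_trajectories["R"][-1] - math.exp(-1)))
        assert round(math.log2(errs[0] / errs[1])) == 4

    def test_violating_configuration_refuses_to_integrate(self, toy):
        with pytest.raises(ConstraintViolation) as exc:
            simulate(toy, "Infeasible", TimeGrid(0, 1, 0.1))
        assert exc.value.error_codes == [101]
        with pytest.raises(ConstraintViolation) as exc:
            simulate(toy, "DoublyInfeasible", TimeGrid(0, 1, 0.1))
        assert exc.value.error_codes == [101, 102]

    def test_determinism_bit_identical(self, seir):
        a = simulate(seir, "HighTransmission", TimeGrid(0, 20, 0.1), seed=9)
        b = simulate(seir, "HighTransmission", TimeGrid(0, 20, 0.1), seed=9)
        for name in a.variable_names:
            assert np.array_equal(a.trajectory(name), b.trajectory(name))

    def test_algebraic_consistency(self, seir):
        res = simulate(seir, "Default", TimeGrid(0, 5, 0.05))
        expr = parse_expression(seir.variable("Prevalence").defining_expression)
        for i, t in enumerate(res.times):
            env = dict(res.parameter_env)
            for name in res.state_trajectories:
                env[name] = res.state_trajectories[name][i]
            assert evaluate(expr, env, t=t) == res.algebraic_trajectories["Prevalence"][i]

    def test_initial_conditions_respected(self, any_fixture):
        res = simulate(any_fixture, "Default", TimeGrid(0, 1, 0.5))
        env = res.parameter_env
        for v in any_fixture.state_variables:
            expected = evaluate(parse_expression(v.initial_condition), env, t=0.0)
            assert res.state_trajectories[v.name][0] == expected

    def test_blow_up_truncates_with_flag(self, toy):
        spec = copy.deepcopy(toy)
        spec.variable("X").defining_expression = "k * X * X"
        spec.variable("X").range_max = None
        spec.parameter("x0").reference_value = 2.0
        spec.parameter("x0").max_admissible = None
        spec.parameter("k").reference_value = 5.0
        # dX/dt = 5 X^2, X(0)=2 blows up at t = 1/10
        res = simulate(spec, "Default", TimeGrid(0.0, 1.0, 0.001))
        assert res.truncated
        assert res.truncated_at is not None and res.truncated_at < 0.2
        assert len(res.times) == len(res.state_trajectories["X"])
        assert np.all(np.isfinite(res.state_trajectories["X"]))

    def test_range_excursions_warn_but_do_not_fail(self, toy):
        spec = copy.deepcopy(toy)
        spec.variable("X").range_max = 1.0  # X starts at 2 -> warning
        res = simulate(spec, "Default", TimeGrid(0, 1, 0.1))
        assert any("exceeded its declared maximum" in w for w in res.warnings)

    def test_csv_round_trip(self, toy, tmp_path):
        import pandas as pd

        res = simulate(toy, "Default", TimeGrid(0, 1, 0.25))
        path = tmp_path / "traj.csv"
        res.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time", "X", "Y"]
        assert np.array_equal(frame["X"].to_numpy(), res.state_trajectories["X"])

    def test_step_forcing_takes_effect(self, toy):
        # dX/dt = -kX + Step(t-1): the unit forcing switches on at t=1
        res = simulate(toy, "Default", TimeGrid(0.0, 5.0, 0.01))
        x = res.state_trajectories["X"]
        t = res.times
        # steady state with forcing is 1/k = 2; without it X decays to 0
        assert x[np.searchsorted(t, 0.99)] < 1.3
        assert x[-1] > 1.5
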