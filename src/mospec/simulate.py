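"""Fixed-step fourth-order Runge-Kutta integration of a validated model.

The model is a mixed algebraic/ODE system: at any (t, state) point the
algebraic variables are evaluated in dependency order, then each state
derivative is evaluated with the algebraic values in scope.  The classical
RK4 tableau advances all states jointly, and the algebraic layer is
re-evaluated at every stage point — freezing it per step would degrade the
scheme below fourth order for mixed systems.

Constraints are predicates over parameters and are checked once, before
integration; a violated constraint refuses to integrate and carries the
declared numeric error codes.  Variable range fields are soft: excursions
are reported as warnings on the result, never as failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .expressions import Expression, parse_expression
from .expressions import evaluate as eval_expr
from .graph import topological_order
from .model import (
    DEFAULT_CONFIGURATION,
    ModelSpec,
    SpecError,
    build_dependency_graph,
    resolve_parameters,
    validate_spec,
)


class ConstraintViolation(RuntimeError):
    """Simulation refused: one or more parameter constraints are false."""

    def __init__(self, error_codes: list[int], configuration: str):
        self.error_codes = list(error_codes)
        self.configuration = configuration
        super().__init__(
            f"configuration '{configuration}' violates constraints; "
            f"error codes {self.error_codes}"
        )


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid {t_start + k*step}, with t_end always the exact final point
    (a shortened last step is taken when the span is not a step multiple)."""

    t_start: float
    t_end: float
    step: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError(f"t_start ({self.t_start}) must precede t_end ({self.t_end})")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")

    def times(self) -> np.ndarray:
        span = self.t_end - self.t_start
        n_full = int(math.floor(span / self.step + 1e-9))
        pts = [self.t_start + k * self.step for k in range(n_full + 1)]
        if abs(pts[-1] - self.t_end) <= 1e-9 * self.step:
            pts[-1] = self.t_end
        elif pts[-1] < self.t_end:
            pts.append(self.t_end)
        return np.asarray(pts, dtype=float)

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "TimeGrid":
        gc = spec.general_controls
        return cls(gc.t_start, gc.t_end, gc.t_step)


@dataclass
class SimulationResult:
    times: np.ndarray
    state_trajectories: dict[str, np.ndarray]
    algebraic_trajectories: dict[str, np.ndarray]
    parameter_env: dict[str, float]
    configuration: str
    seed: int
    truncated: bool = False
    truncated_at: float | None = None
    warnings: list[str] = field(default_factory=list)

    def trajectory(self, name: str) -> np.ndarray:
        if name in self.state_trajectories:
            return self.state_trajectories[name]
        if name in self.algebraic_trajectories:
            return self.algebraic_trajectories[name]
        raise KeyError(f"no trajectory for '{name}'")

    @property
    def variable_names(self) -> list[str]:
        return list(self.state_trajectories) + list(self.algebraic_trajectories)

    def to_dataframe(self):
        import pandas as pd

        data = {"time": self.times}
        for name in self.variable_names:
            data[name] = self.trajectory(name)
        return pd.DataFrame(data)

    def to_csv(self, path) -> str:
        """Headered CSV: time column plus one column per variable, written
        with 17 significant digits so values round-trip exactly."""
        with open(path, "w", newline="") as fh:
            fh.write(",".join(["time"] + self.variable_names) + "\n")
            for i in range(len(self.times)):
                row = [self.times[i]] + [self.trajectory(n)[i] for n in self.variable_names]
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
        return str(path)


# ---------------------------------------------------------------------------


def rk4_step(derivative, t: float, state: np.ndarray, h: float) -> np.ndarray:
    """One classical four-stage step: stages at t, t+h/2, t+h/2, t+h.

    Raises on a non-finite derivative, naming the offending time.
    """
    k1 = np.asarray(derivative(t, state), dtype=float)
    k2 = np.asarray(derivative(t + 0.5 * h, state + 0.5 * h * k1), dtype=float)
    k3 = np.asarray(derivative(t + 0.5 * h, state + 0.5 * h * k2), dtype=float)
    k4 = np.asarray(derivative(t + h, state + h * k3), dtype=float)
    for label, k in (("k1", k1), ("k2", k2), ("k3", k3), ("k4", k4)):
        if not np.all(np.isfinite(k)):
            raise FloatingPointError(f"non-finite derivative ({label}) at t={t}")
    return state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def check_constraints(spec: ModelSpec, env: dict[str, float]) -> list[int]:
    """Error codes of all violated constraints, in declaration order."""
    violated: list[int] = []
    for i, c in enumerate(spec.constraints, start=1):
        try:
            expr = parse_expression(c.predicate)
            value = eval_expr(expr, env)
        except Exception as exc:
            raise SpecError(f"constraint #{i} cannot be evaluated: {exc}")
        if value == 0.0:
            violated.append(c.error_code)
    return violated


class _CompiledModel:
    """Parsed expressions plus evaluation order, reused across stages."""

    def __init__(self, spec: ModelSpec):
        self.state_names = [v.name for v in spec.state_variables]
        self.algebraic_names = [v.name for v in spec.algebraic_variables]
        g = build_dependency_graph(spec)
        order = topological_order(g)
        self.algebraic_order = [n for n in order if n in set(self.algebraic_names)]
        self.algebraic_exprs: dict[str, Expression] = {
            v.name: parse_expression(v.defining_expression)
            for v in spec.algebraic_variables
        }
        self.derivative_exprs: dict[str, Expression] = {
            v.name: parse_expression(v.defining_expression)
            for v in spec.state_variables
        }
        self.initial_exprs: dict[str, Expression] = {
            v.name: parse_expression(v.initial_condition)
            for v in spec.state_variables
        }

    def algebraic_env(self, t, state_vec, params, rng) -> dict[str, float]:
        env = dict(params)
        for name, value in zip(self.state_names, state_vec):
            env[name] = float(value)
        for name in self.algebraic_order:
            env[name] = eval_expr(self.algebraic_exprs[name], env, t=t, rng=rng)
        return env

    def derivatives(self, t, state_vec, params, rng) -> np.ndarray:
        env = self.algebraic_env(t, state_vec, params, rng)
        return np.array(
            [eval_expr(self.derivative_exprs[n], env, t=t, rng=rng) for n in self.state_names],
            dtype=float,
        )


def simulate(
    spec: ModelSpec,
    configuration: str = DEFAULT_CONFIGURATION,
    grid: TimeGrid | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Integrate ``spec`` under one configuration over ``grid``.

    The spec must be valid and the configuration's resolved parameters must
    satisfy every constraint (:class:`ConstraintViolation` otherwise, with
    the declared error codes and no integration performed).  If the state
    goes non-finite, the trajectory is truncated at the last finite point
    and the result is flagged, so partial runs remain plottable.
    """
    problems = [d for d in validate_spec(spec) if d.severity == "error"]
    if problems:
        raise SpecError(
            "spec is not valid:\n" + "\n".join(str(d) for d in problems)
        )
    if grid is None:
        grid = TimeGrid.from_spec(spec)

    rng = np.random.default_rng(seed)
    params = resolve_parameters(spec, configuration, rng=rng)
    violated = check_constraints(spec, params)
    if violated:
        raise ConstraintViolation(violated, configuration)

    compiled = _CompiledModel(spec)
    times = grid.times()
    n = len(times)
    n_states = len(compiled.state_names)

    state = np.array(
        [
            eval_expr(compiled.initial_exprs[name], params, t=times[0], rng=rng)
            for name in compiled.state_names
        ],
        dtype=float,
    )

    states = np.full((n, n_states), np.nan)
    algebraics = np.full((n, len(compiled.algebraic_names)), np.nan)
    truncated = False
    truncated_at = None

    def record(i: int, t: float, vec: np.ndarray) -> None:
        states[i, :] = vec
        env = compiled.algebraic_env(t, vec, params, rng)
        for j, name in enumerate(compiled.algebraic_names):
            algebraics[i, j] = env[name]

    record(0, times[0], state)
    last = 0
    for i in range(1, n):
        h = times[i] - times[i - 1]
        try:
            state = rk4_step(
                lambda tt, y: compiled.derivatives(tt, y, params, rng),
                times[i - 1],
                state,
                h,
            )
        except FloatingPointError:
            truncated, truncated_at = True, float(times[i])
            break
        if not np.all(np.isfinite(state)):
            truncated, truncated_at = True, float(times[i])
            break
        record(i, times[i], state)
        last = i

    if truncated:
        times = times[: last + 1]
        states = states[: last + 1]
        algebraics = algebraics[: last + 1]

    result = SimulationResult(
        times=times,
        state_trajectories={
            name: states[:, j].copy() for j, name in enumerate(compiled.state_names)
        },
        algebraic_trajectories={
            name: algebraics[:, j].copy()
            for j, name in enumerate(compiled.algebraic_names)
        },
        parameter_env=params,
        configuration=configuration,
        seed=seed,
        truncated=truncated,
        truncated_at=truncated_at,
    )
    _range_warnings(spec, result)
    return result


def _range_warnings(spec: ModelSpec, result: SimulationResult) -> None:
    for v in spec.variables:
        if v.name not in result.variable_names:
            continue
        traj = result.trajectory(v.name)
        if v.range_min is not None and np.nanmin(traj) < v.range_min:
            result.warnings.append(
                f"variable '{v.name}' fell below its declared minimum "
                f"{v.range_min} (reached {np.nanmin(traj):.6g})"
            )
        if v.range_max is not None and np.nanmax(traj) > v.range_max:
            result.warnings.append(
                f"variable '{v.name}' exceeded its declared maximum "
                f"{v.range_max} (reached {np.nanmax(traj):.6g})"
            )
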