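"""Emission of runnable model packages in the target dialects.

For a valid spec, :func:`generate_package` writes one folder per dialect
containing the same five routines under the same names — ``ModelPars``
(parameter resolution per configuration), ``ModelRHS`` / ``AlgebraicValues``
/ ``InitialConditions`` (the model proper), ``RK4Step`` / ``TimeGrid`` /
``Integrate`` (the fixed-step fourth-order Runge-Kutta driver),
``CheckConstraints``, and the ``<ProjectName>AutoTester`` entry script that
simulates the "Default" configuration over the GeneralControls grid, writes
a trajectory CSV and plots the variable time courses.

Every generated file carries a header with the spec's version string and no
timestamps, so regeneration from an unchanged spec is byte-identical.  The
emitted integrator replicates the in-process scheme operation for
operation (same grid construction, same stage arithmetic, same expression
parenthesisation), which is what makes the host-dialect output agree with
in-process simulation to machine precision — the system's "twins" property.

:func:`write_dat_files` emits the two structural data files
``<ProjectName>.modpars.dat`` and ``<ProjectName>.vars.dat`` (headered TSV,
one record per parameter/variable).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .dialects import DEFAULT_DIALECTS, DialectTable
from .expressions import parse_expression, render
from .graph import topological_order
from .model import ModelSpec, SpecError, build_dependency_graph, version_string


class CodegenError(ValueError):
    pass


@dataclass
class GeneratedPackage:
    dialect_id: str
    files: dict[str, str]  # relative file name -> text content
    entry_point: str

    def write(self, directory) -> str:
        os.makedirs(directory, exist_ok=True)
        for name, content in self.files.items():
            with open(os.path.join(directory, name), "w", newline="\n") as fh:
                fh.write(content)
        return str(directory)


# ---------------------------------------------------------------------------
# shared rendering context


class _Context:
    def __init__(self, spec: ModelSpec, dialect: DialectTable):
        self.spec = spec
        self.dialect = dialect
        self.project = spec.meta.project_name
        self.version = version_string(spec.meta)
        self.cm = dialect.comment_prefix
        self.ext = dialect.source_extension

        g = build_dependency_graph(spec)
        order = topological_order(g)
        det = {p.name: p for p in spec.determined_parameters}
        alg = {v.name: v for v in spec.algebraic_variables}

        self.free_params = [(p.name, float(p.reference_value)) for p in spec.free_parameters]
        self.determined = [
            (n, self._r(det[n].defining_expression)) for n in order if n in det
        ]
        self.algebraic = [(n, self._r(alg[n].defining_expression)) for n in order if n in alg]
        self.states = [
            (v.name, self._r(v.defining_expression), self._r(v.initial_condition))
            for v in spec.state_variables
        ]
        self.all_param_names = [p.name for p in spec.parameters]
        self.constraints = [(c.error_code, self._r(c.predicate)) for c in spec.constraints]
        self.configs = [(c.name, dict(c.overrides)) for c in spec.effective_configurations()]
        gc = spec.general_controls
        self.t_start, self.t_end, self.t_step = gc.t_start, gc.t_end, gc.t_step
        display = gc.default_display_variables or [v.name for v in spec.state_variables]
        self.display_vars = display
        self.var_names = [v.name for v in spec.state_variables] + [
            v.name for v in spec.algebraic_variables
        ]
        self.state_names = [v.name for v in spec.state_variables]
        self.algebraic_names = [v.name for v in spec.algebraic_variables]

    def _r(self, source: str) -> str:
        return render(parse_expression(source), self.dialect)

    def header(self, routine: str) -> list[str]:
        return [
            f"{self.cm} {routine}",
            f"{self.cm} Generated by the mospec Autocoder from {self.version}",
            f"{self.cm} Do not edit: regenerate from the model workbook instead.",
        ]


def _esc(text: str) -> str:
    """Descriptive text placed in comments/strings: keep it on one line and
    free of quote characters (prevents workbook text from injecting code)."""
    return str(text).replace("\n", " ").replace('"', "'").replace("\\", "/")


def _num(value: float) -> str:
    return repr(float(value))


# ---------------------------------------------------------------------------
# python emitter


def _py_files(ctx: _Context) -> dict[str, str]:
    P = ctx.project
    files = {}

    lines = ctx.header(f"{P}ModelPars{ctx.ext} - parameter resolution") + [
        "",
        "import math",
        "import random as _random",
        "",
        "_unif = _random.Random(0)",
        "",
        "",
        "def SeedModel(seed):",
        "    _unif.seed(seed)",
        "",
        "",
        "def RandUnif():",
        "    return _unif.random()",
        "",
        "",
        "def Step(x):",
        "    return 1.0 if x >= 0.0 else 0.0",
        "",
        "",
        "CONFIGURATION_NAMES = ["
        + ", ".join(f'"{name}"' for name, _ in ctx.configs)
        + "]",
        "",
        "",
        'def ModelPars(configuration="Default"):',
        "    if configuration not in CONFIGURATION_NAMES:",
        '        raise ValueError("unknown configuration: " + configuration)',
        "    # free parameters: reference values",
    ]
    for name, ref in ctx.free_params:
        lines.append(f"    {name} = {_num(ref)}")
    for cname, overrides in ctx.configs:
        if not overrides:
            continue
        lines.append(f'    if configuration == "{cname}":')
        for pname, value in overrides.items():
            lines.append(f"        {pname} = {_num(value)}")
    if ctx.determined:
        lines.append("    # determined parameters, in dependency order")
        for name, expr in ctx.determined:
            lines.append(f"    {name} = {expr}")
    mapping = ", ".join(f'"{n}": {n}' for n in ctx.all_param_names)
    lines += ["    return {" + mapping + "}", ""]
    files[f"{P}ModelPars{ctx.ext}"] = "\n".join(lines) + "\n"

    unpack = [f'    {n} = pars["{n}"]' for n in ctx.all_param_names]
    ystates = [f"    {n} = y[{i}]" for i, n in enumerate(ctx.state_names)]
    alg_lines = [f"    {n} = {e}" for n, e in ctx.algebraic]
    lines = ctx.header(f"{P}ModelRHS{ctx.ext} - model right-hand side") + [
        "",
        "import math",
        "",
        f"from {P}ModelPars import RandUnif, Step",
        "",
        "STATE_NAMES = [" + ", ".join(f'"{n}"' for n in ctx.state_names) + "]",
        "ALGEBRAIC_NAMES = [" + ", ".join(f'"{n}"' for n in ctx.algebraic_names) + "]",
        "",
        "",
        "def AlgebraicValues(t, y, pars):",
        *unpack,
        *ystates,
        *alg_lines,
        "    return [" + ", ".join(n for n, _ in ctx.algebraic) + "]",
        "",
        "",
        "def ModelRHS(t, y, pars):",
        *unpack,
        *ystates,
        *alg_lines,
        *[f"    d_{n} = {e}" for n, e, _ in ctx.states],
        "    return [" + ", ".join(f"d_{n}" for n, _, _ in ctx.states) + "]",
        "",
        "",
        "def InitialConditions(pars, t):",
        *unpack,
        "    return [" + ", ".join(ic for _, _, ic in ctx.states) + "]",
        "",
    ]
    files[f"{P}ModelRHS{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"RK4Solver{ctx.ext} - fixed-step fourth-order Runge-Kutta") + [
        "",
        "import math",
        "",
        "",
        "def TimeGrid(t0, t1, step):",
        "    n_full = int(math.floor((t1 - t0) / step + 1e-9))",
        "    times = [t0 + k * step for k in range(n_full + 1)]",
        "    if abs(times[-1] - t1) <= 1e-9 * step:",
        "        times[-1] = t1",
        "    elif times[-1] < t1:",
        "        times.append(t1)",
        "    return times",
        "",
        "",
        "def RK4Step(f, t, y, h):",
        "    n = len(y)",
        "    k1 = f(t, y)",
        "    k2 = f(t + 0.5 * h, [y[i] + 0.5 * h * k1[i] for i in range(n)])",
        "    k3 = f(t + 0.5 * h, [y[i] + 0.5 * h * k2[i] for i in range(n)])",
        "    k4 = f(t + h, [y[i] + h * k3[i] for i in range(n)])",
        "    return [y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])"
        " for i in range(n)]",
        "",
        "",
        "def Integrate(f, times, y0):",
        "    states = [list(y0)]",
        "    y = list(y0)",
        "    for i in range(1, len(times)):",
        "        y = RK4Step(f, times[i - 1], y, times[i] - times[i - 1])",
        "        states.append(list(y))",
        "    return states",
        "",
    ]
    files[f"RK4Solver{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}ConstraintCheck{ctx.ext} - parameter constraint checks") + [
        "",
        "import math",
        "",
        f"from {P}ModelPars import RandUnif, Step",
        "",
        "",
        "def CheckConstraints(pars):",
        *unpack,
        "    violated = []",
    ]
    for code, pred in ctx.constraints:
        lines += [f"    if ({pred}) == 0:", f"        violated.append({code})"]
    lines += ["    return violated", ""]
    files[f"{P}ConstraintCheck{ctx.ext}"] = "\n".join(lines) + "\n"

    header_names = ", ".join(["time"] + ctx.var_names)
    lines = ctx.header(f"{P}AutoTester{ctx.ext} - entry point") + [
        "",
        "import sys",
        "",
        f"from {P}ConstraintCheck import CheckConstraints",
        f"from {P}ModelPars import ModelPars",
        f"from {P}ModelRHS import AlgebraicValues, InitialConditions, ModelRHS",
        "from RK4Solver import Integrate, TimeGrid",
        "",
        f"T_START = {_num(ctx.t_start)}",
        f"T_END = {_num(ctx.t_end)}",
        f"T_STEP = {_num(ctx.t_step)}",
        "",
        "",
        "def main():",
        '    pars = ModelPars("Default")',
        "    violated = CheckConstraints(pars)",
        "    if violated:",
        '        print("constraint violation; error codes:", violated)',
        "        sys.exit(3)",
        "    times = TimeGrid(T_START, T_END, T_STEP)",
        "    y0 = InitialConditions(pars, times[0])",
        "    states = Integrate(lambda tt, yy: ModelRHS(tt, yy, pars), times, y0)",
        f'    with open("{P}_trajectory.csv", "w") as fh:',
        f'        fh.write("{",".join(["time"] + ctx.var_names)}\\n")',
        "        for i, ti in enumerate(times):",
        "            alg = AlgebraicValues(ti, states[i], pars)",
        "            row = [ti] + list(states[i]) + list(alg)",
        '            fh.write(",".join("%.17g" % v for v in row) + "\\n")',
        '    print("wrote ' + P + '_trajectory.csv (%d points)" % len(times))',
        "    try:",
        "        import matplotlib",
        '        matplotlib.use("Agg")',
        "        import matplotlib.pyplot as plt",
        "        names = STATE_AND_ALGEBRAIC",
        "        fig, axes = plt.subplots(len(DISPLAY), 1, figsize=(7, 2.5 * len(DISPLAY)))",
        "        if len(DISPLAY) == 1:",
        "            axes = [axes]",
        "        for ax, name in zip(axes, DISPLAY):",
        "            j = names.index(name)",
        "            series = [",
        "                ([ti] + list(states[i]) + list(AlgebraicValues(ti, states[i], pars)))[j + 1]",
        "                for i, ti in enumerate(times)",
        "            ]",
        "            ax.plot(times, series)",
        "            ax.set_ylabel(name)",
        '        axes[-1].set_xlabel("time")',
        "        fig.tight_layout()",
        f'        fig.savefig("{P}_plot.png")',
        '        print("wrote ' + P + '_plot.png")',
        "    except Exception as exc:",
        '        print("plotting skipped:", exc)',
        "",
        "",
        "STATE_AND_ALGEBRAIC = [" + ", ".join(f'"{n}"' for n in ctx.var_names) + "]",
        "DISPLAY = [" + ", ".join(f'"{n}"' for n in ctx.display_vars) + "]",
        "",
        'if __name__ == "__main__":',
        "    main()",
        "",
    ]
    del header_names
    files[f"{P}AutoTester{ctx.ext}"] = "\n".join(lines) + "\n"
    return files


# ---------------------------------------------------------------------------
# R emitter
#
# Generated functions shadow base names when a parameter is called e.g. `c`,
# so every use of base concatenation is namespaced as base::c.


def _r_files(ctx: _Context) -> dict[str, str]:
    P = ctx.project
    files = {}
    unpack = [f'  {n} <- pars[["{n}"]]' for n in ctx.all_param_names]
    ystates = [f"  {n} <- y[[{i + 1}]]" for i, n in enumerate(ctx.state_names)]
    alg_lines = [f"  {n} <- {e}" for n, e in ctx.algebraic]

    lines = ctx.header(f"{P}ModelPars{ctx.ext} - parameter resolution") + [
        "",
        "Step <- function(x) {",
        "  if (x >= 0) 1.0 else 0.0",
        "}",
        "",
        "RandUnif <- function() {",
        "  runif(1)",
        "}",
        "",
        "SeedModel <- function(seed) {",
        "  set.seed(seed)",
        "}",
        "",
        "CONFIGURATION_NAMES <- base::c("
        + ", ".join(f'"{name}"' for name, _ in ctx.configs)
        + ")",
        "",
        'ModelPars <- function(configuration = "Default") {',
        "  if (!(configuration %in% CONFIGURATION_NAMES)) {",
        '    stop(paste("unknown configuration:", configuration))',
        "  }",
        "  # free parameters: reference values",
    ]
    for name, ref in ctx.free_params:
        lines.append(f"  {name} <- {_num(ref)}")
    for cname, overrides in ctx.configs:
        if not overrides:
            continue
        lines.append(f'  if (configuration == "{cname}") {{')
        for pname, value in overrides.items():
            lines.append(f"    {pname} <- {_num(value)}")
        lines.append("  }")
    if ctx.determined:
        lines.append("  # determined parameters, in dependency order")
        for name, expr in ctx.determined:
            lines.append(f"  {name} <- {expr}")
    mapping = ", ".join(f"{n} = {n}" for n in ctx.all_param_names)
    lines += ["  list(" + mapping + ")", "}", ""]
    files[f"{P}ModelPars{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}ModelRHS{ctx.ext} - model right-hand side") + [
        "",
        "STATE_NAMES <- base::c(" + ", ".join(f'"{n}"' for n in ctx.state_names) + ")",
        "ALGEBRAIC_NAMES <- base::c("
        + ", ".join(f'"{n}"' for n in ctx.algebraic_names)
        + ")",
        "",
        "AlgebraicValues <- function(t, y, pars) {",
        *unpack,
        *ystates,
        *alg_lines,
        "  base::c(" + ", ".join(n for n, _ in ctx.algebraic) + ")",
        "}",
        "",
        "ModelRHS <- function(t, y, pars) {",
        *unpack,
        *ystates,
        *alg_lines,
        *[f"  d_{n} <- {e}" for n, e, _ in ctx.states],
        "  base::c(" + ", ".join(f"d_{n}" for n, _, _ in ctx.states) + ")",
        "}",
        "",
        "InitialConditions <- function(pars, t) {",
        *unpack,
        "  base::c(" + ", ".join(ic for _, _, ic in ctx.states) + ")",
        "}",
        "",
    ]
    files[f"{P}ModelRHS{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"RK4Solver{ctx.ext} - fixed-step fourth-order Runge-Kutta") + [
        "",
        "TimeGrid <- function(t0, t1, step) {",
        "  n_full <- floor((t1 - t0) / step + 1e-9)",
        "  times <- t0 + (0:n_full) * step",
        "  last <- length(times)",
        "  if (abs(times[last] - t1) <= 1e-9 * step) {",
        "    times[last] <- t1",
        "  } else if (times[last] < t1) {",
        "    times <- base::c(times, t1)",
        "  }",
        "  times",
        "}",
        "",
        "RK4Step <- function(f, t, y, h) {",
        "  k1 <- f(t, y)",
        "  k2 <- f(t + 0.5 * h, y + 0.5 * h * k1)",
        "  k3 <- f(t + 0.5 * h, y + 0.5 * h * k2)",
        "  k4 <- f(t + h, y + h * k3)",
        "  y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)",
        "}",
        "",
        "Integrate <- function(f, times, y0) {",
        "  states <- matrix(0.0, nrow = length(times), ncol = length(y0))",
        "  states[1, ] <- y0",
        "  y <- y0",
        "  for (i in 2:length(times)) {",
        "    y <- RK4Step(f, times[i - 1], y, times[i] - times[i - 1])",
        "    states[i, ] <- y",
        "  }",
        "  states",
        "}",
        "",
    ]
    files[f"RK4Solver{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}ConstraintCheck{ctx.ext} - parameter constraint checks") + [
        "",
        "CheckConstraints <- function(pars) {",
        *unpack,
        "  violated <- base::c()",
    ]
    for code, pred in ctx.constraints:
        lines += [
            f"  if (({pred}) == 0) {{",
            f"    violated <- base::c(violated, {code})",
            "  }",
        ]
    lines += ["  violated", "}", ""]
    files[f"{P}ConstraintCheck{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}AutoTester{ctx.ext} - entry point") + [
        "",
        f'source("{P}ModelPars{ctx.ext}")',
        f'source("{P}ModelRHS{ctx.ext}")',
        f'source("{P}ConstraintCheck{ctx.ext}")',
        f'source("RK4Solver{ctx.ext}")',
        "",
        f"T_START <- {_num(ctx.t_start)}",
        f"T_END <- {_num(ctx.t_end)}",
        f"T_STEP <- {_num(ctx.t_step)}",
        "",
        'pars <- ModelPars("Default")',
        "violated <- CheckConstraints(pars)",
        "if (length(violated) > 0) {",
        '  cat("constraint violation; error codes:", violated, "\\n")',
        "  quit(status = 3)",
        "}",
        "times <- TimeGrid(T_START, T_END, T_STEP)",
        "y0 <- InitialConditions(pars, times[1])",
        "states <- Integrate(function(tt, yy) ModelRHS(tt, yy, pars), times, y0)",
        "rows <- character(length(times))",
        "for (i in seq_along(times)) {",
        "  alg <- AlgebraicValues(times[i], states[i, ], pars)",
        "  row <- base::c(times[i], states[i, ], alg)",
        '  rows[i] <- paste(sprintf("%.17g", row), collapse = ",")',
        "}",
        'header <- "' + ",".join(["time"] + ctx.var_names) + '"',
        f'writeLines(base::c(header, rows), "{P}_trajectory.csv")',
        f'cat("wrote {P}_trajectory.csv (", length(times), " points)\\n")',
        "ok <- try({",
        f'  pdf("{P}_plot.pdf")',
        '  matplot(times, states, type = "l", lty = 1, xlab = "time", ylab = "state variables")',
        "  legend(\"topright\", legend = STATE_NAMES, col = seq_along(STATE_NAMES), lty = 1)",
        "  dev.off()",
        f'  cat("wrote {P}_plot.pdf\\n")',
        "}, silent = TRUE)",
        "",
    ]
    files[f"{P}AutoTester{ctx.ext}"] = "\n".join(lines) + "\n"
    return files


# ---------------------------------------------------------------------------
# Julia emitter


def _jl_files(ctx: _Context) -> dict[str, str]:
    P = ctx.project
    files = {}
    unpack = [f'    {n} = pars["{n}"]' for n in ctx.all_param_names]
    ystates = [f"    {n} = y[{i + 1}]" for i, n in enumerate(ctx.state_names)]
    alg_lines = [f"    {n} = {e}" for n, e in ctx.algebraic]

    lines = ctx.header(f"{P}ModelPars{ctx.ext} - parameter resolution") + [
        "",
        "import Random",
        "",
        "const _unif = Random.MersenneTwister(0)",
        "",
        "SeedModel(seed) = Random.seed!(_unif, seed)",
        "",
        "RandUnif() = rand(_unif)",
        "",
        "Step(x) = x >= 0.0 ? 1.0 : 0.0",
        "",
        "const CONFIGURATION_NAMES = ["
        + ", ".join(f'"{name}"' for name, _ in ctx.configs)
        + "]",
        "",
        'function ModelPars(configuration::String = "Default")',
        "    if !(configuration in CONFIGURATION_NAMES)",
        '        error("unknown configuration: " * configuration)',
        "    end",
        "    # free parameters: reference values",
    ]
    for name, ref in ctx.free_params:
        lines.append(f"    {name} = {_num(ref)}")
    for cname, overrides in ctx.configs:
        if not overrides:
            continue
        lines.append(f'    if configuration == "{cname}"')
        for pname, value in overrides.items():
            lines.append(f"        {pname} = {_num(value)}")
        lines.append("    end")
    if ctx.determined:
        lines.append("    # determined parameters, in dependency order")
        for name, expr in ctx.determined:
            lines.append(f"    {name} = {expr}")
    mapping = ", ".join(f'"{n}" => {n}' for n in ctx.all_param_names)
    lines += ["    Dict{String,Float64}(" + mapping + ")", "end", ""]
    files[f"{P}ModelPars{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}ModelRHS{ctx.ext} - model right-hand side") + [
        "",
        "const STATE_NAMES = [" + ", ".join(f'"{n}"' for n in ctx.state_names) + "]",
        "const ALGEBRAIC_NAMES = ["
        + ", ".join(f'"{n}"' for n in ctx.algebraic_names)
        + "]",
        "",
        "function AlgebraicValues(t, y, pars)",
        *unpack,
        *ystates,
        *alg_lines,
        "    Float64[" + ", ".join(n for n, _ in ctx.algebraic) + "]",
        "end",
        "",
        "function ModelRHS(t, y, pars)",
        *unpack,
        *ystates,
        *alg_lines,
        *[f"    d_{n} = {e}" for n, e, _ in ctx.states],
        "    Float64[" + ", ".join(f"d_{n}" for n, _, _ in ctx.states) + "]",
        "end",
        "",
        "function InitialConditions(pars, t)",
        *unpack,
        "    Float64[" + ", ".join(ic for _, _, ic in ctx.states) + "]",
        "end",
        "",
    ]
    files[f"{P}ModelRHS{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"RK4Solver{ctx.ext} - fixed-step fourth-order Runge-Kutta") + [
        "",
        "function TimeGrid(t0, t1, step)",
        "    n_full = floor(Int, (t1 - t0) / step + 1e-9)",
        "    times = [t0 + k * step for k in 0:n_full]",
        "    if abs(times[end] - t1) <= 1e-9 * step",
        "        times[end] = t1",
        "    elseif times[end] < t1",
        "        push!(times, t1)",
        "    end",
        "    times",
        "end",
        "",
        "function RK4Step(f, t, y, h)",
        "    k1 = f(t, y)",
        "    k2 = f(t + 0.5 * h, y .+ 0.5 .* h .* k1)",
        "    k3 = f(t + 0.5 * h, y .+ 0.5 .* h .* k2)",
        "    k4 = f(t + h, y .+ h .* k3)",
        "    y .+ (h / 6.0) .* (k1 .+ 2.0 .* k2 .+ 2.0 .* k3 .+ k4)",
        "end",
        "",
        "function Integrate(f, times, y0)",
        "    states = zeros(length(times), length(y0))",
        "    states[1, :] = y0",
        "    y = copy(y0)",
        "    for i in 2:length(times)",
        "        y = RK4Step(f, times[i - 1], y, times[i] - times[i - 1])",
        "        states[i, :] = y",
        "    end",
        "    states",
        "end",
        "",
    ]
    files[f"RK4Solver{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}ConstraintCheck{ctx.ext} - parameter constraint checks") + [
        "",
        "function CheckConstraints(pars)",
        *unpack,
        "    violated = Int[]",
    ]
    for code, pred in ctx.constraints:
        lines += [
            f"    if ({pred}) == 0",
            f"        push!(violated, {code})",
            "    end",
        ]
    lines += ["    violated", "end", ""]
    files[f"{P}ConstraintCheck{ctx.ext}"] = "\n".join(lines) + "\n"

    lines = ctx.header(f"{P}AutoTester{ctx.ext} - entry point") + [
        "",
        "using Printf",
        "",
        f'include("{P}ModelPars{ctx.ext}")',
        f'include("{P}ModelRHS{ctx.ext}")',
        f'include("{P}ConstraintCheck{ctx.ext}")',
        f'include("RK4Solver{ctx.ext}")',
        "",
        f"const T_START = {_num(ctx.t_start)}",
        f"const T_END = {_num(ctx.t_end)}",
        f"const T_STEP = {_num(ctx.t_step)}",
        "",
        'pars = ModelPars("Default")',
        "violated = CheckConstraints(pars)",
        "if !isempty(violated)",
        '    println("constraint violation; error codes: ", violated)',
        "    exit(3)",
        "end",
        "times = TimeGrid(T_START, T_END, T_STEP)",
        "y0 = InitialConditions(pars, times[1])",
        "states = Integrate((tt, yy) -> ModelRHS(tt, yy, pars), times, y0)",
        f'open("{P}_trajectory.csv", "w") do fh',
        '    println(fh, "' + ",".join(["time"] + ctx.var_names) + '")',
        "    for i in eachindex(times)",
        "        alg = AlgebraicValues(times[i], states[i, :], pars)",
        "        row = vcat(times[i], states[i, :], alg)",
        '        println(fh, join([@sprintf("%.17g", v) for v in row], ","))',
        "    end",
        "end",
        f'println("wrote {P}_trajectory.csv (", length(times), " points)")',
        "# plotting requires the Plots package; skipped when unavailable",
        "try",
        "    @eval using Plots",
        "    plt = plot(times, states, label = permutedims(STATE_NAMES), xlabel = \"time\")",
        f'    savefig(plt, "{P}_plot.png")',
        f'    println("wrote {P}_plot.png")',
        "catch err",
        '    println("plotting skipped: ", err)',
        "end",
        "",
    ]
    files[f"{P}AutoTester{ctx.ext}"] = "\n".join(lines) + "\n"
    return files


_EMITTERS = {"python": _py_files, "r": _r_files, "julia": _jl_files}


def generate_package(spec: ModelSpec, dialect, out_dir) -> GeneratedPackage:
    """Emit a runnable model package for one dialect under ``out_dir``.

    ``dialect`` is a :class:`DialectTable` or a dialect id.  The package is
    written to ``out_dir/<dialect_id>/``; the returned object also carries
    every file as text.  Raises :class:`CodegenError` for a dialect without
    an emitter and propagates unmapped-builtin rendering errors.
    """
    if isinstance(dialect, str):
        table = spec.dialect_map.get(dialect) or DEFAULT_DIALECTS.get(dialect)
        if table is None:
            raise CodegenError(f"unknown dialect '{dialect}'")
    else:
        table = dialect
    if table.dialect_id not in _EMITTERS:
        raise CodegenError(
            f"no package emitter for dialect '{table.dialect_id}' "
            f"(available: {sorted(_EMITTERS)})"
        )
    ctx = _Context(spec, table)
    files = _EMITTERS[table.dialect_id](ctx)
    entry = f"{ctx.project}AutoTester{ctx.ext}"
    if entry not in files:
        raise CodegenError("emitter produced no entry point")  # pragma: no cover
    pkg = GeneratedPackage(dialect_id=table.dialect_id, files=files, entry_point=entry)
    if out_dir is not None:
        pkg.write(os.path.join(str(out_dir), table.dialect_id))
    return pkg


# ---------------------------------------------------------------------------
# structural .dat files


def write_dat_files(spec: ModelSpec, out_dir) -> tuple[str, str]:
    """Write ``<ProjectName>.modpars.dat`` and ``<ProjectName>.vars.dat``.

    Headered tab-separated text, one record per parameter/variable; blank
    fields are empty cells.  :func:`read_dat_files` parses them back.
    """
    os.makedirs(out_dir, exist_ok=True)
    P = spec.meta.project_name

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, float):
            return f"{value:.17g}"
        return _esc(value).replace("\t", " ")

    modpars = os.path.join(str(out_dir), f"{P}.modpars.dat")
    with open(modpars, "w", newline="\n") as fh:
        fh.write("Name\tKind\tValueOrDefinition\tMin\tMax\tUnit\tDescription\n")
        for p in spec.parameters:
            value = (
                p.reference_value if p.kind == "free" else p.defining_expression
            )
            fh.write(
                "\t".join(
                    fmt(x)
                    for x in (
                        p.name, p.kind, value, p.min_admissible, p.max_admissible,
                        p.unit, p.description,
                    )
                )
                + "\n"
            )

    vars_path = os.path.join(str(out_dir), f"{P}.vars.dat")
    with open(vars_path, "w", newline="\n") as fh:
        fh.write("Name\tKind\tMin\tMax\tUnit\tDescription\tInitialCondition\n")
        for v in spec.variables:
            fh.write(
                "\t".join(
                    fmt(x)
                    for x in (
                        v.name, v.kind, v.range_min, v.range_max, v.unit,
                        v.description, v.initial_condition,
                    )
                )
                + "\n"
            )
    return modpars, vars_path


def read_dat_files(out_dir, project_name: str) -> tuple[list[dict], list[dict]]:
    """Parse the two structural files back into lists of field dicts."""

    def load(path) -> list[dict]:
        with open(path) as fh:
            lines = [line.rstrip("\n") for line in fh]
        if not lines:
            raise SpecError(f"{path} is empty")
        header = lines[0].split("\t")
        records = []
        for line in lines[1:]:
            if not line.strip():
                continue
            cells = line.split("\t")
            cells += [""] * (len(header) - len(cells))
            records.append(dict(zip(header, cells)))
        return records

    modpars = load(os.path.join(str(out_dir), f"{project_name}.modpars.dat"))
    variables = load(os.path.join(str(out_dir), f"{project_name}.vars.dat"))
    return modpars, variables
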