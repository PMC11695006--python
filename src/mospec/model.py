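"""Domain types for a complete model specification, plus validation and
parameter resolution.

A :class:`ModelSpec` is the in-memory image of one model workbook: project
metadata, variables (state or algebraic), parameters (free or determined),
parameter constraints, named parameter-vector configurations, the dialect
tables, and the document/simulation controls.  ``validate_spec`` enforces
every structural invariant and never raises — all problems come back as
:class:`Diagnostic` records naming the offending sheet and location.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import graph as depgraph
from .dialects import DialectTable
from .expressions import (
    BUILTINS,
    TIME_SYMBOL,
    EvaluationError,
    Expression,
    ExpressionSyntaxError,
    parse_expression,
)

# variable kinds
STATE = "state"
ALGEBRAIC = "algebraic"
# parameter kinds
FREE = "free"
DETERMINED = "determined"

DEFAULT_CONFIGURATION = "Default"

# canonical obligatory sheet names, in workbook order
SHEET_TITLES = "1-Titles"
SHEET_VARIABLES = "2-Variables"
SHEET_PARAMETERS = "3-Parameters"
SHEET_CONSTRAINTS = "4-Constraints"
SHEET_CONFIGURATIONS = "5-Configurations"
SHEET_LATEX = "6-LaTeXControls"
SHEET_CPP = "7-SpecialCPPCode"
SHEET_ML = "8-SpecialMLCode"
SHEET_R = "9-SpecialRCode"
SHEET_JULIA = "10-SpecialJuliaCode"
SHEET_GENERAL = "11-GeneralControls"

OBLIGATORY_SHEETS = (
    SHEET_TITLES,
    SHEET_VARIABLES,
    SHEET_PARAMETERS,
    SHEET_CONSTRAINTS,
    SHEET_CONFIGURATIONS,
    SHEET_LATEX,
    SHEET_CPP,
    SHEET_ML,
    SHEET_R,
    SHEET_JULIA,
    SHEET_GENERAL,
)

#: quadrant cap of the plotting surface; display-variable lists may not exceed it
PLOT_QUADRANT_COUNT = 8

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class SpecError(ValueError):
    """A precondition on an already-validated spec was broken at call time."""


@dataclass
class ModelMeta:
    project_name: str
    model_version: int = 0
    implementation_subversion: int = 0
    edition_subsubversion: int = 0
    dates: str = ""
    changelog: list[str] = field(default_factory=list)


@dataclass
class VariableDef:
    name: str
    unit: str = ""
    description: str = ""
    range_min: float | None = None  # None = unbounded
    range_max: float | None = None
    kind: str = STATE
    defining_expression: str = ""
    initial_condition: str | None = None  # present iff kind == state
    latex_name: str = ""


@dataclass
class ParameterDef:
    name: str
    unit: str = ""
    description: str = ""
    kind: str = FREE
    reference_value: float | None = None  # present iff kind == free
    min_admissible: float | None = None
    max_admissible: float | None = None
    defining_expression: str | None = None  # present iff kind == determined
    latex_name: str = ""


@dataclass
class ConstraintDef:
    predicate: str
    error_code: int
    latex_text: str = ""


@dataclass
class ConfigurationDef:
    name: str
    overrides: dict[str, float] = field(default_factory=dict)


@dataclass
class FigureEntry:
    file_name: str
    caption: str = ""
    label: str = ""


@dataclass
class LatexControls:
    table_cell_length: str = "6cm"
    name_column_length: str = "2.5cm"
    figure_entries: list[FigureEntry] = field(default_factory=list)


@dataclass
class GeneralControls:
    default_display_variables: list[str] = field(default_factory=list)
    default_datasets: list[str] = field(default_factory=list)
    t_start: float = 0.0
    t_end: float = 10.0
    t_step: float = 0.01


@dataclass
class ModelSpec:
    meta: ModelMeta
    variables: list[VariableDef] = field(default_factory=list)
    parameters: list[ParameterDef] = field(default_factory=list)
    constraints: list[ConstraintDef] = field(default_factory=list)
    configurations: list[ConfigurationDef] = field(default_factory=list)
    dialects: list[DialectTable] = field(default_factory=list)
    latex_controls: LatexControls = field(default_factory=LatexControls)
    general_controls: GeneralControls = field(default_factory=GeneralControls)
    notes: str = ""

    # --- convenience lookups -------------------------------------------

    def variable(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise SpecError(f"no variable named '{name}'")

    def parameter(self, name: str) -> ParameterDef:
        for p in self.parameters:
            if p.name == name:
                return p
        raise SpecError(f"no parameter named '{name}'")

    @property
    def state_variables(self) -> list[VariableDef]:
        return [v for v in self.variables if v.kind == STATE]

    @property
    def algebraic_variables(self) -> list[VariableDef]:
        return [v for v in self.variables if v.kind == ALGEBRAIC]

    @property
    def free_parameters(self) -> list[ParameterDef]:
        return [p for p in self.parameters if p.kind == FREE]

    @property
    def determined_parameters(self) -> list[ParameterDef]:
        return [p for p in self.parameters if p.kind == DETERMINED]

    def effective_configurations(self) -> list[ConfigurationDef]:
        """Declared configurations, with "Default" synthesized if absent."""
        configs = list(self.configurations)
        if not any(c.name == DEFAULT_CONFIGURATION for c in configs):
            configs.insert(0, ConfigurationDef(DEFAULT_CONFIGURATION, {}))
        return configs

    def configuration(self, name: str) -> ConfigurationDef:
        for c in self.effective_configurations():
            if c.name == name:
                return c
        raise SpecError(f"no configuration named '{name}'")

    @property
    def dialect_map(self) -> dict[str, DialectTable]:
        return {d.dialect_id: d for d in self.dialects}


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    sheet: str
    location: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.sheet} / {self.location}: {self.message}"


# ---------------------------------------------------------------------------
# Version naming


def version_string(meta: ModelMeta) -> str:
    """Canonical workbook name: ``<project>.MoSpec V<vv>.<vv>.<vv>``."""
    return (
        f"{meta.project_name}.MoSpec "
        f"V{meta.model_version:02d}."
        f"{meta.implementation_subversion:02d}."
        f"{meta.edition_subsubversion:02d}"
    )


# ---------------------------------------------------------------------------
# Dependency graph construction


def _parse_or_none(source: str | None) -> Expression | None:
    if source is None or not str(source).strip():
        return None
    try:
        return parse_expression(source)
    except ExpressionSyntaxError:
        return None


def build_dependency_graph(spec: ModelSpec) -> depgraph.DependencyGraph:
    """Reference graph over all defined quantities.

    One node per free/determined parameter, per variable, plus derivative
    nodes (``X'``) and initial-condition nodes (``X(0)``) for states; edge
    u -> v whenever v's name appears in u's definition.  Unparseable
    definitions contribute a node but no edges (validation reports them
    separately).
    """
    g = depgraph.DependencyGraph()
    known = {p.name for p in spec.parameters} | {v.name for v in spec.variables}

    for p in spec.free_parameters:
        g.add_node(p.name, depgraph.FREE)
    for v in spec.state_variables:
        g.add_node(v.name, depgraph.STATE)

    def wire(node_name: str, source: str | None) -> None:
        expr = _parse_or_none(source)
        if expr is None:
            return
        for ident in sorted(expr.free_identifiers()):
            if ident in known:
                g.add_edge(node_name, ident)

    for p in spec.determined_parameters:
        g.add_node(p.name, depgraph.DETERMINED)
        wire(p.name, p.defining_expression)
    for v in spec.algebraic_variables:
        g.add_node(v.name, depgraph.ALGEBRAIC)
        wire(v.name, v.defining_expression)
    for v in spec.state_variables:
        g.add_node(f"{v.name}'", depgraph.DERIVATIVE)
        wire(f"{v.name}'", v.defining_expression)
        g.add_node(f"{v.name}(0)", depgraph.INITIAL)
        wire(f"{v.name}(0)", v.initial_condition)
    return g


# ---------------------------------------------------------------------------
# Validation


def validate_spec(spec: ModelSpec) -> list[Diagnostic]:
    """Check every structural invariant; returns all violations found.

    An empty list means the spec is valid.  Problems are never raised:
    workbooks arrive from humans and every defect should surface at once.
    """
    diags: list[Diagnostic] = []

    def err(sheet: str, location: str, message: str) -> None:
        diags.append(Diagnostic("error", sheet, location, message))

    # --- metadata ------------------------------------------------------
    name = spec.meta.project_name
    if not name or not _IDENT_RE.match(name):
        err(SHEET_TITLES, "ProjectName", f"project name {name!r} is not a valid identifier")
    elif "/" in name or "\\" in name:
        err(SHEET_TITLES, "ProjectName", "project name must not contain path separators")
    for label, v in (
        ("ModelVersion", spec.meta.model_version),
        ("ImplementationSubversion", spec.meta.implementation_subversion),
        ("EditionSubsubversion", spec.meta.edition_subsubversion),
    ):
        if not isinstance(v, int) or v < 0:
            err(SHEET_TITLES, label, f"{label} must be a non-negative integer, got {v!r}")

    # --- name table ----------------------------------------------------
    seen: dict[str, str] = {}
    for v in spec.variables:
        _check_name(v.name, SHEET_VARIABLES, f"variable {v.name!r}", seen, err)
    for p in spec.parameters:
        _check_name(p.name, SHEET_PARAMETERS, f"parameter {p.name!r}", seen, err)

    param_names = {p.name for p in spec.parameters}
    var_names = {v.name for v in spec.variables}
    known = param_names | var_names

    def check_expr(
        sheet: str,
        location: str,
        source: str | None,
        *,
        allow: set[str],
        allow_time: bool,
        role: str,
    ) -> None:
        if source is None or not str(source).strip():
            return
        try:
            expr = parse_expression(source)
        except ExpressionSyntaxError as exc:
            err(sheet, location, f"syntax error in {role}: {exc}")
            return
        for ident in sorted(expr.free_identifiers()):
            if ident not in allow:
                what = (
                    "may not be referenced here"
                    if ident in known
                    else "is not a declared parameter or variable"
                )
                err(sheet, location, f"identifier '{ident}' {what}")
        for fn in sorted(expr.function_names()):
            if fn not in BUILTINS:
                err(sheet, location, f"unknown function '{fn}'")
        if not allow_time and expr.references_time():
            err(sheet, location, f"the time symbol '{TIME_SYMBOL}' may not appear in {role}")

    # --- variables -----------------------------------------------------
    if not spec.state_variables:
        err(SHEET_VARIABLES, "(sheet)", "at least one state variable is required")
    for v in spec.variables:
        loc = f"variable {v.name!r}"
        if v.kind not in (STATE, ALGEBRAIC):
            err(SHEET_VARIABLES, loc, f"kind must be '{STATE}' or '{ALGEBRAIC}', got {v.kind!r}")
            continue
        if v.range_min is not None and v.range_max is not None and v.range_min > v.range_max:
            err(SHEET_VARIABLES, loc, f"range min {v.range_min} exceeds range max {v.range_max}")
        has_ic = v.initial_condition is not None and str(v.initial_condition).strip() != ""
        if v.kind == STATE and not has_ic:
            err(SHEET_VARIABLES, loc, "state variables require an initial condition")
        if v.kind == ALGEBRAIC and has_ic:
            err(SHEET_VARIABLES, loc, "algebraic variables must not declare an initial condition")
        if not str(v.defining_expression).strip():
            err(SHEET_VARIABLES, loc, "defining pseudocode is missing")
        else:
            check_expr(
                SHEET_VARIABLES, loc, v.defining_expression,
                allow=known, allow_time=True, role="the defining expression",
            )
        if has_ic:
            # initial conditions may use parameters (and the start time),
            # never other variables: states are undefined before t0.
            check_expr(
                SHEET_VARIABLES, f"{loc} initial condition", v.initial_condition,
                allow=param_names, allow_time=True, role="an initial condition",
            )

    # --- parameters ----------------------------------------------------
    for p in spec.parameters:
        loc = f"parameter {p.name!r}"
        if p.kind not in (FREE, DETERMINED):
            err(SHEET_PARAMETERS, loc, f"kind must be '{FREE}' or '{DETERMINED}', got {p.kind!r}")
            continue
        has_expr = p.defining_expression is not None and str(p.defining_expression).strip() != ""
        if p.kind == FREE:
            if p.reference_value is None:
                err(SHEET_PARAMETERS, loc, "free parameters require a reference value")
            if has_expr:
                err(SHEET_PARAMETERS, loc, "free parameters must not carry a defining expression")
            if (
                p.reference_value is not None
                and p.min_admissible is not None
                and p.reference_value < p.min_admissible
            ):
                err(SHEET_PARAMETERS, loc, "reference value below admissible minimum")
            if (
                p.reference_value is not None
                and p.max_admissible is not None
                and p.reference_value > p.max_admissible
            ):
                err(SHEET_PARAMETERS, loc, "reference value above admissible maximum")
        else:
            if not has_expr:
                err(SHEET_PARAMETERS, loc, "determined parameters require a defining expression")
            if p.reference_value is not None:
                err(SHEET_PARAMETERS, loc, "determined parameters must not carry a reference value")
            # determined parameters are functions of parameters only: they
            # are fixed before integration, so no states, no time.
            check_expr(
                SHEET_PARAMETERS, loc, p.defining_expression,
                allow=param_names, allow_time=False,
                role="a determined-parameter definition",
            )
        if (
            p.min_admissible is not None
            and p.max_admissible is not None
            and p.min_admissible > p.max_admissible
        ):
            err(SHEET_PARAMETERS, loc, "admissible minimum exceeds admissible maximum")

    # --- constraints ---------------------------------------------------
    codes_seen: dict[int, int] = {}
    for i, c in enumerate(spec.constraints, start=1):
        loc = f"constraint #{i}"
        if not isinstance(c.error_code, int):
            err(SHEET_CONSTRAINTS, loc, f"error code must be an integer, got {c.error_code!r}")
        elif c.error_code in codes_seen:
            err(
                SHEET_CONSTRAINTS, loc,
                f"error code {c.error_code} already used by constraint #{codes_seen[c.error_code]}",
            )
        else:
            codes_seen[c.error_code] = i
        check_expr(
            SHEET_CONSTRAINTS, loc, c.predicate,
            allow=param_names, allow_time=False, role="a constraint predicate",
        )
        if not str(c.predicate).strip():
            err(SHEET_CONSTRAINTS, loc, "constraint predicate is missing")

    # --- configurations ------------------------------------------------
    config_names: set[str] = set()
    for c in spec.configurations:
        loc = f"configuration {c.name!r}"
        if c.name in config_names:
            err(SHEET_CONFIGURATIONS, loc, "duplicate configuration name")
        config_names.add(c.name)
        for pname in c.overrides:
            if pname not in param_names:
                err(SHEET_CONFIGURATIONS, loc, f"override targets unknown parameter '{pname}'")
            elif spec.parameter(pname).kind == DETERMINED:
                err(
                    SHEET_CONFIGURATIONS, loc,
                    f"override targets determined parameter '{pname}' "
                    "(determined parameters are computed, not set)",
                )

    # --- LaTeX controls ------------------------------------------------
    for f in spec.latex_controls.figure_entries:
        if "/" in f.file_name or "\\" in f.file_name:
            err(SHEET_LATEX, f"figure {f.file_name!r}", "figure file names must not contain path separators")

    # --- general controls ----------------------------------------------
    gc = spec.general_controls
    for dv in gc.default_display_variables:
        if dv not in var_names:
            err(SHEET_GENERAL, "DisplayVariable", f"'{dv}' is not a declared variable")
    if len(gc.default_display_variables) > PLOT_QUADRANT_COUNT:
        err(
            SHEET_GENERAL, "DisplayVariable",
            f"at most {PLOT_QUADRANT_COUNT} display variables are supported, "
            f"got {len(gc.default_display_variables)}",
        )
    if not gc.t_start < gc.t_end:
        err(SHEET_GENERAL, "TStart/TEnd", f"t_start ({gc.t_start}) must precede t_end ({gc.t_end})")
    if not 0 < gc.t_step <= (gc.t_end - gc.t_start):
        err(SHEET_GENERAL, "TStep", f"t_step ({gc.t_step}) must be in (0, t_end - t_start]")

    # --- dependency cycles ---------------------------------------------
    g = build_dependency_graph(spec)
    for cycle in sorted(g.cycles()):
        members = ", ".join(sorted(cycle))
        err(
            SHEET_VARIABLES if any(n in var_names for n in cycle) else SHEET_PARAMETERS,
            "(dependency graph)",
            f"cyclic definitions among {{{members}}}",
        )

    return diags


def _check_name(name: str, sheet: str, location: str, seen: dict[str, str], err) -> None:
    if not name or not _IDENT_RE.match(str(name)):
        err(sheet, location, f"{name!r} is not a valid identifier")
        return
    if name == TIME_SYMBOL:
        err(sheet, location, f"'{TIME_SYMBOL}' is reserved for simulation time")
        return
    if name in seen:
        err(sheet, location, f"name '{name}' already declared as {seen[name]}")
        return
    seen[name] = location


# ---------------------------------------------------------------------------
# Parameter resolution


def resolve_parameters(
    spec: ModelSpec, configuration: str = DEFAULT_CONFIGURATION, rng=None
) -> dict[str, float]:
    """Complete parameter environment for one configuration.

    Free parameters take their reference values, overridden by the
    configuration; determined parameters are then computed in dependency
    order, so declaration order never matters.  Raises :class:`SpecError`
    for an unknown configuration or an evaluation failure (naming the
    offending parameter).
    """
    config = spec.configuration(configuration)  # raises SpecError if unknown
    env: dict[str, float] = {}
    for p in spec.free_parameters:
        if p.reference_value is None:
            raise SpecError(f"free parameter '{p.name}' has no reference value")
        env[p.name] = float(p.reference_value)
    for pname, value in config.overrides.items():
        env[pname] = float(value)

    g = build_dependency_graph(spec)
    determined = {p.name: p for p in spec.determined_parameters}
    order = depgraph.topological_order(g)
    for qname in order:
        if qname not in determined:
            continue
        p = determined[qname]
        try:
            expr = parse_expression(p.defining_expression or "")
            env[p.name] = float(evaluate_expr(expr, env, rng=rng))
        except (ExpressionSyntaxError, EvaluationError) as exc:
            raise SpecError(f"cannot compute determined parameter '{p.name}': {exc}")
    return env


def evaluate_expr(expr: Expression, env: dict[str, float], t=None, rng=None) -> float:
    from .expressions import evaluate

    return evaluate(expr, env, t=t, rng=rng)
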