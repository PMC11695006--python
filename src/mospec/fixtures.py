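"""Bundled example models, constructed programmatically.

Three small models exercise every feature of the specification format:

``TwoLovers``
    A Rinaldi-style linear model of mutual attraction between two people:
    dR/dt = a*R + b*J, dJ/dt = c*R + d*J.  Linear and analytically solvable,
    so it doubles as the closed-form oracle for the integrator (its
    "Decoupled" configuration reduces each state to pure exponential decay).

``SEIR``
    A single-node Susceptible-Exposed-Infectious-Removed epidemic model.
    Its four derivatives sum identically to zero, making total population a
    conserved quantity — the conservation test for the integrator — and it
    carries a determined basic-reproduction-number parameter and a
    positivity constraint (error code 201).

``ConstrainedToy``
    One state with a step-function forcing, one algebraic cap variable, two
    constraints and a figure entry: touches every sheet of the workbook,
    including deliberately violating configurations for constraint tests.
"""

from __future__ import annotations

from .dialects import CPP, JULIA, MATLAB, R
from .model import (
    ConfigurationDef,
    ConstraintDef,
    FigureEntry,
    GeneralControls,
    LatexControls,
    ModelMeta,
    ModelSpec,
    ParameterDef,
    VariableDef,
)

FIXTURE_NAMES = ("TwoLovers", "SEIR", "ConstrainedToy")


def make_fixture(name: str) -> ModelSpec:
    """Return one of the bundled example models by name."""
    if name == "TwoLovers":
        return _two_lovers()
    if name == "SEIR":
        return _seir()
    if name == "ConstrainedToy":
        return _constrained_toy()
    raise KeyError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")


def _sheet_dialects():
    return [CPP, MATLAB, R, JULIA]


def _two_lovers() -> ModelSpec:
    return ModelSpec(
        meta=ModelMeta(
            project_name="TwoLovers",
            model_version=2,
            implementation_subversion=4,
            edition_subsubversion=3,
            dates="started 2024-05-01",
            changelog=["initial linear dynamics", "added TotalAffection"],
        ),
        variables=[
            VariableDef(
                name="R", unit="affection units", description="Romeo's affection for Juliet",
                range_min=-10.0, range_max=10.0, kind="state",
                defining_expression="a*R + b*J", initial_condition="R0",
                latex_name="R",
            ),
            VariableDef(
                name="J", unit="affection units", description="Juliet's affection for Romeo",
                range_min=-10.0, range_max=10.0, kind="state",
                defining_expression="c*R + d*J", initial_condition="J0",
                latex_name="J",
            ),
            VariableDef(
                name="TotalAffection", unit="affection units",
                description="combined affection of the couple",
                kind="algebraic", defining_expression="R + J",
                latex_name="A_{tot}",
            ),
        ],
        parameters=[
            ParameterDef(
                name="a", unit="1/day", description="Romeo's response to his own feelings",
                kind="free", reference_value=-0.2, min_admissible=-5.0, max_admissible=5.0,
                latex_name="a",
            ),
            ParameterDef(
                name="b", unit="1/day", description="Romeo's response to Juliet's affection",
                kind="free", reference_value=0.6, min_admissible=-5.0, max_admissible=5.0,
                latex_name="b",
            ),
            ParameterDef(
                name="c", unit="1/day", description="Juliet's response to Romeo's affection",
                kind="free", reference_value=-0.4, min_admissible=-5.0, max_admissible=5.0,
                latex_name="c",
            ),
            ParameterDef(
                name="d", unit="1/day", description="Juliet's response to her own feelings",
                kind="free", reference_value=-0.1, min_admissible=-5.0, max_admissible=5.0,
                latex_name="d",
            ),
            ParameterDef(
                name="R0", unit="affection units", description="Romeo's initial affection",
                kind="free", reference_value=1.0, latex_name="R_0",
            ),
            ParameterDef(
                name="J0", unit="affection units", description="Juliet's initial affection",
                kind="free", reference_value=1.0, latex_name="J_0",
            ),
            ParameterDef(
                name="CouplingGain", unit="1/day^2",
                description="product of the cross-coupling coefficients; negative values give oscillatory courtship",
                kind="determined", defining_expression="b * c",
                latex_name="\\kappa",
            ),
        ],
        constraints=[],
        configurations=[
            ConfigurationDef("Default", {}),
            ConfigurationDef(
                "Decoupled", {"a": -1.0, "b": 0.0, "c": 0.0, "d": -1.0}
            ),
            ConfigurationDef("JulietIndifferent", {"c": 0.0, "d": 0.0, "J0": 0.0}),
        ],
        dialects=_sheet_dialects(),
        latex_controls=LatexControls(),
        general_controls=GeneralControls(
            default_display_variables=["R", "J", "TotalAffection"],
            t_start=0.0, t_end=20.0, t_step=0.01,
        ),
        notes="Linear attraction dynamics in the style of Rinaldi's romantic-relationship models.",
    )


def _seir() -> ModelSpec:
    return ModelSpec(
        meta=ModelMeta(
            project_name="SEIR",
            model_version=1,
            implementation_subversion=0,
            edition_subsubversion=2,
            dates="started 2024-06-10",
            changelog=["single-node compartmental structure"],
        ),
        variables=[
            VariableDef(
                name="S", unit="individuals", description="susceptible individuals",
                range_min=0.0, kind="state",
                defining_expression="-beta * S * I / N",
                initial_condition="S_init", latex_name="S",
            ),
            VariableDef(
                name="E", unit="individuals", description="exposed (incubating) individuals",
                range_min=0.0, kind="state",
                defining_expression="beta * S * I / N - sigma * E",
                initial_condition="E_init", latex_name="E",
            ),
            VariableDef(
                name="I", unit="individuals", description="infectious individuals",
                range_min=0.0, kind="state",
                defining_expression="sigma * E - gamma * I",
                initial_condition="I_init", latex_name="I",
            ),
            VariableDef(
                name="R", unit="individuals", description="removed (recovered or deceased) individuals",
                range_min=0.0, kind="state",
                defining_expression="gamma * I",
                initial_condition="0", latex_name="R",
            ),
            VariableDef(
                name="Prevalence", unit="fraction",
                description="infectious fraction of the population",
                kind="algebraic", defining_expression="I / N",
                latex_name="p",
            ),
        ],
        parameters=[
            ParameterDef(
                name="beta", unit="1/day", description="transmission rate",
                kind="free", reference_value=0.3, min_admissible=0.0, max_admissible=5.0,
                latex_name="\\beta",
            ),
            ParameterDef(
                name="sigma", unit="1/day", description="incubation rate (1/latent period)",
                kind="free", reference_value=0.2, min_admissible=0.0, max_admissible=5.0,
                latex_name="\\sigma",
            ),
            ParameterDef(
                name="gamma", unit="1/day", description="removal rate (1/infectious period)",
                kind="free", reference_value=0.1, min_admissible=0.0, max_admissible=5.0,
                latex_name="\\gamma",
            ),
            ParameterDef(
                name="S_init", unit="individuals", description="initial susceptibles",
                kind="free", reference_value=990.0, min_admissible=0.0,
                latex_name="S(0)",
            ),
            ParameterDef(
                name="E_init", unit="individuals", description="initial exposed",
                kind="free", reference_value=10.0, min_admissible=0.0,
                latex_name="E(0)",
            ),
            ParameterDef(
                name="I_init", unit="individuals", description="initial infectious",
                kind="free", reference_value=0.0, min_admissible=0.0,
                latex_name="I(0)",
            ),
            ParameterDef(
                name="N", unit="individuals", description="total population size",
                kind="determined", defining_expression="S_init + E_init + I_init",
                latex_name="N",
            ),
            ParameterDef(
                name="BasicReproduction", unit="dimensionless",
                description="basic reproduction number of the epidemic",
                kind="determined", defining_expression="beta / gamma",
                latex_name="\\mathcal{R}_0",
            ),
        ],
        constraints=[
            ConstraintDef(
                predicate="beta > 0 and sigma > 0 and gamma > 0",
                error_code=201,
                latex_text="All epidemiological rates must be strictly positive.",
            ),
        ],
        configurations=[
            ConfigurationDef("Default", {}),
            ConfigurationDef("HighTransmission", {"beta": 0.6}),
            ConfigurationDef("NegativeRemoval", {"gamma": -0.1}),  # violates 201 on purpose
        ],
        dialects=_sheet_dialects(),
        latex_controls=LatexControls(),
        general_controls=GeneralControls(
            default_display_variables=["S", "E", "I", "R"],
            t_start=0.0, t_end=160.0, t_step=0.05,
        ),
        notes="Single-node SEIR stand-in for a multinode epidemic model.",
    )


def _constrained_toy() -> ModelSpec:
    return ModelSpec(
        meta=ModelMeta(
            project_name="ConstrainedToy",
            model_version=0,
            implementation_subversion=1,
            edition_subsubversion=0,
            dates="started 2024-07-01",
            changelog=["toy exerciser for every sheet"],
        ),
        variables=[
            VariableDef(
                name="X", unit="a.u.", description="decaying quantity with a step input at t = 1",
                range_min=0.0, range_max=100.0, kind="state",
                defining_expression="-k * X + Step(t - 1)",
                initial_condition="x0", latex_name="X",
            ),
            VariableDef(
                name="Y", unit="a.u.", description="X clipped at the cap",
                kind="algebraic", defining_expression="Min(X, cap)",
                latex_name="Y",
            ),
        ],
        parameters=[
            ParameterDef(
                name="k", unit="1/s", description="decay rate",
                kind="free", reference_value=0.5, min_admissible=-10.0, max_admissible=10.0,
                latex_name="k",
            ),
            ParameterDef(
                name="x0", unit="a.u.", description="initial value of X",
                kind="free", reference_value=2.0, min_admissible=0.0, max_admissible=100.0,
                latex_name="x_0",
            ),
            ParameterDef(
                name="cap", unit="a.u.", description="clipping threshold for Y",
                kind="free", reference_value=10.0, min_admissible=0.0, max_admissible=100.0,
                latex_name="c",
            ),
            ParameterDef(
                name="HalfLife", unit="s", description="half-life implied by the decay rate",
                kind="determined", defining_expression="Ln(2) / k",
                latex_name="t_{1/2}",
            ),
        ],
        constraints=[
            ConstraintDef(
                predicate="k > 0", error_code=101,
                latex_text="The decay rate must be positive.",
            ),
            ConstraintDef(
                predicate="cap > x0", error_code=102,
                latex_text="The cap must exceed the initial value.",
            ),
        ],
        configurations=[
            ConfigurationDef("Default", {}),
            ConfigurationDef("Infeasible", {"k": -1.0}),  # violates 101 (and breaks HalfLife sign)
            ConfigurationDef("DoublyInfeasible", {"k": -1.0, "cap": 1.0}),  # violates 101 and 102
            ConfigurationDef("FastDecay", {"k": 2.0}),
        ],
        dialects=_sheet_dialects(),
        latex_controls=LatexControls(
            table_cell_length="5.5cm",
            name_column_length="2cm",
            figure_entries=[
                FigureEntry(
                    file_name="toy_diagram.png",
                    caption="Block diagram of the toy model.",
                    label="fig:toy",
                )
            ],
        ),
        general_controls=GeneralControls(
            default_display_variables=["X", "Y"],
            default_datasets=["toy_observations.csv"],
            t_start=0.0, t_end=5.0, t_step=0.01,
        ),
        notes="Exercises constraints, algebraic clipping, time-dependent forcing and figures.",
    )
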