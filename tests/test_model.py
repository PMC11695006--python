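"""Spec validation, parameter resolution and version naming."""

import copy

import pytest

from mospec.model import (
    ConfigurationDef, ConstraintDef, ModelMeta, ModelSpec, ParameterDef,
    SpecError, VariableDef, resolve_parameters, validate_spec, version_string,
)


def _errors(spec):
    return [d for d in validate_spec(spec) if d.severity == "error"]


class TestVersionString:
    @pytest.mark.parametrize(
        "name,v,s,e,expected",
        [
            ("RomanticLove", 2, 4, 3, "RomanticLove.MoSpec V02.04.03"),
            ("X", 0, 0, 0, "X.MoSpec V00.00.00"),
            ("Corona", 12, 3, 10, "Corona.MoSpec V12.03.10"),
        ],
    )
    def test_zero_padded_triples(self, name, v, s, e, expected):
        meta = ModelMeta(project_name=name, model_version=v,
                         implementation_subversion=s, edition_subsubversion=e)
        assert version_string(meta) == expected


class TestValidation:
    def test_fixtures_are_valid(self, any_fixture):
        assert validate_spec(any_fixture) == []

    def test_validation_is_idempotent(self, two_lovers):
        assert validate_spec(two_lovers) == validate_spec(two_lovers)

    def test_override_of_determined_parameter_cites_configurations_sheet(self, two_lovers):
        two_lovers.configurations.append(
            ConfigurationDef("Bad", {"CouplingGain": 1.0})
        )
        errors = _errors(two_lovers)
        assert len(errors) == 1
        assert errors[0].sheet == "5-Configurations"
        assert "CouplingGain" in errors[0].message

    def test_self_referential_algebraic_is_a_cycle(self, two_lovers):
        two_lovers.variables.append(
            VariableDef(name="A", kind="algebraic", defining_expression="A + 1")
        )
        errors = _errors(two_lovers)
        assert any("cyclic" in e.message and "A" in e.message for e in errors)

    def test_state_requires_initial_condition(self, two_lovers):
        two_lovers.variables[0].initial_condition = None
        assert any("initial condition" in e.message for e in _errors(two_lovers))

    def test_free_parameter_requires_reference_value(self, two_lovers):
        two_lovers.parameters[0].reference_value = None
        assert any("reference value" in e.message for e in _errors(two_lovers))

    def test_determined_parameter_may_not_use_state_or_time(self, two_lovers):
        two_lovers.parameters.append(
            ParameterDef(name="badA", kind="determined", defining_expression="R + 1")
        )
        two_lovers.parameters.append(
            ParameterDef(name="badB", kind="determined", defining_expression="t + 1")
        )
        messages = " | ".join(e.message for e in _errors(two_lovers))
        assert "'R' may not be referenced here" in messages
        assert "time symbol" in messages

    def test_constraint_may_not_reference_variables(self, seir):
        seir.constraints.append(ConstraintDef(predicate="S > 0", error_code=300))
        assert any("'S' may not be referenced here" in e.message for e in _errors(seir))

    def test_duplicate_error_codes_rejected(self, toy):
        toy.constraints.append(ConstraintDef(predicate="k < 100", error_code=101))
        assert any("already used" in e.message for e in _errors(toy))

    def test_duplicate_names_rejected(self, two_lovers):
        two_lovers.parameters.append(
            ParameterDef(name="R", kind="free", reference_value=1.0)
        )
        assert any("already declared" in e.message for e in _errors(two_lovers))

    def test_unknown_identifier_reported(self, two_lovers):
        two_lovers.variables[0].defining_expression = "a*R + ghost"
        assert any("ghost" in e.message for e in _errors(two_lovers))

    def test_unparseable_expression_reported(self, two_lovers):
        two_lovers.variables[0].defining_expression = "a*(R"
        assert any("syntax error" in e.message for e in _errors(two_lovers))

    def test_display_variable_limit(self, two_lovers):
        two_lovers.general_controls.default_display_variables = ["R"] * 9
        assert any("at most 8" in e.message for e in _errors(two_lovers))

    def test_time_grid_invariants(self, two_lovers):
        two_lovers.general_controls.t_end = two_lovers.general_controls.t_start
        assert any("must precede" in e.message for e in _errors(two_lovers))

    def test_range_order_checked(self, toy):
        toy.variables[0].range_min = 5.0
        toy.variables[0].range_max = 1.0
        assert any("exceeds range max" in e.message for e in _errors(toy))


class TestResolveParameters:
    def _spec(self, params, configs=()):
        return ModelSpec(
            meta=ModelMeta(project_name="P"),
            variables=[VariableDef(name="X", kind="state",
                                   defining_expression="0", initial_condition="1")],
            parameters=params,
            configurations=list(configs),
        )

    def test_override_feeds_determined(self):
        spec = self._spec(
            [
                ParameterDef(name="a", kind="free", reference_value=2.0),
                ParameterDef(name="b", kind="determined", defining_expression="2*a"),
            ],
            [ConfigurationDef("Boost", {"a": 5.0})],
        )
        assert resolve_parameters(spec, "Boost") == {"a": 5.0, "b": 10.0}

    def test_declaration_order_is_irrelevant(self):
        defs = [
            ParameterDef(name="c", kind="determined", defining_expression="b+1"),
            ParameterDef(name="b", kind="determined", defining_expression="2*a"),
            ParameterDef(name="a", kind="free", reference_value=3.0),
        ]
        expected = {"a": 3.0, "b": 6.0, "c": 7.0}
        import itertools

        for perm in itertools.permutations(defs):
            assert resolve_parameters(self._spec(list(perm))) == expected

    def test_default_uses_reference_values(self, seir):
        env = resolve_parameters(seir, "Default")
        for p in seir.free_parameters:
            assert env[p.name] == p.reference_value
        assert env["N"] == 1000.0
        assert env["BasicReproduction"] == pytest.approx(3.0)

    def test_environment_is_complete(self, any_fixture):
        env = resolve_parameters(any_fixture)
        assert set(env) == {p.name for p in any_fixture.parameters}

    def test_unknown_configuration_raises(self, two_lovers):
        with pytest.raises(SpecError, match="Nope"):
            resolve_parameters(two_lovers, "Nope")

    def test_failing_determined_names_parameter(self):
        spec = self._spec(
            [
                ParameterDef(name="a", kind="free", reference_value=0.0),
                ParameterDef(name="q", kind="determined", defining_expression="1/a"),
            ]
        )
        with pytest.raises(SpecError, match="'q'"):
            resolve_parameters(spec)

    def test_missing_default_is_synthesized(self, two_lovers):
        two_lovers.configurations = [c for c in two_lovers.configurations
                                     if c.name != "Default"]
        assert validate_spec(two_lovers) == []
        env = resolve_parameters(two_lovers, "Default")
        assert env["a"] == -0.2
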