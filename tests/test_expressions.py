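"""Pseudocode engine: parsing, precedence, evaluation, dialect rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mospec.dialects import DEFAULT_DIALECTS, JULIA, PSEUDOCODE, PYTHON, R, DialectTable
from mospec.expressions import (
    Bin, Call, Cmp, If, Neg, Num, Ref,
    EvaluationError, ExpressionSyntaxError, RenderError,
    evaluate, parse_expression, python_runtime_env, random_expression, render,
)


class TestParsing:
    def test_precedence_textbook_case(self):
        root = parse_expression("a*X + b").root
        assert root == Bin("+", Bin("*", Ref("a"), Ref("X")), Ref("b"))

    def test_nullary_call(self):
        assert parse_expression("RandUnif()").root == Call("RandUnif", ())

    def test_power_is_right_associative(self):
        # oracle: fully parenthesised re-statement must give the same tree
        assert parse_expression("-(a^b^c)").root == parse_expression("-(a^(b^c))").root
        assert parse_expression("-(a^b^c)").root == Neg(
            Bin("^", Ref("a"), Bin("^", Ref("b"), Ref("c")))
        )

    def test_unary_minus_binds_looser_than_power(self):
        assert parse_expression("-x^2").root == Neg(Bin("^", Ref("x"), Num(2.0)))

    def test_conditional_and_comparison(self):
        root = parse_expression("If(x >= 1, x, 0)").root
        assert root == If(Cmp(">=", Ref("x"), Num(1.0)), Ref("x"), Num(0.0))

    def test_equals_alias(self):
        assert parse_expression("a = 1").root == parse_expression("a == 1").root

    @pytest.mark.parametrize(
        "bad",
        ["", "   ", "a +", "(a", "a)", "1 < 2 < 3", "Min(a,)", "If(a, b)", "2..5", "a $ b"],
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(ExpressionSyntaxError):
            parse_expression(bad)

    def test_error_carries_position(self):
        with pytest.raises(ExpressionSyntaxError) as exc:
            parse_expression("a + $")
        assert exc.value.position == 4

    @given(st.integers(0, 6))
    @settings(max_examples=20, deadline=None)
    def test_whitespace_insignificant(self, pad):
        spaced = (" " * pad).join(["-", "a", "*", "(", "b", "+", "2", ")"])
        assert parse_expression(spaced).root == parse_expression("-a*(b+2)").root


class TestEvaluation:
    def test_simple_arithmetic(self):
        assert evaluate(parse_expression("2*a"), {"a": 5}) == 10

    def test_builtin_combination(self):
        expr = parse_expression("Min(a, b) + Abs(-3)")
        assert evaluate(expr, {"a": 1, "b": 7}) == 4

    def test_randunif_is_seed_deterministic(self):
        expr = parse_expression("RandUnif()")
        draws = [
            evaluate(expr, {}, rng=np.random.default_rng(42)) for _ in range(2)
        ]
        assert draws[0] == draws[1]
        assert 0.0 <= draws[0] < 1.0

    def test_conditional_evaluates_taken_branch_only(self):
        expr = parse_expression("If(a > 0, a, 1/0)")
        assert evaluate(expr, {"a": 2}) == 2  # untaken division by zero untouched

    def test_truth_values_are_unit(self):
        assert evaluate(parse_expression("(a < b) * 10"), {"a": 1, "b": 2}) == 10
        assert evaluate(parse_expression("not (1 > 2)"), {}) == 1.0

    @pytest.mark.parametrize(
        "source,env",
        [("1/0", {}), ("Ln(-1)", {}), ("Sqrt(-4)", {}), ("x + 1", {}), ("Foo(1)", {})],
    )
    def test_evaluation_errors(self, source, env):
        with pytest.raises(EvaluationError):
            evaluate(parse_expression(source), env)

    def test_unbound_identifier_is_named(self):
        with pytest.raises(EvaluationError, match="mystery"):
            evaluate(parse_expression("mystery + 1"), {})

    def test_step_semantics(self):
        step = parse_expression("Step(x)")
        assert evaluate(step, {"x": 0.0}) == 1.0
        assert evaluate(step, {"x": -1e-12}) == 0.0


class TestRendering:
    def test_custom_function_map(self):
        table = DialectTable(dialect_id="custom", function_map={"RandUnif": "runif"})
        assert render(parse_expression("RandUnif()"), table) == "runif()"

    @pytest.mark.parametrize("dialect", list(DEFAULT_DIALECTS.values()))
    def test_identifier_is_identity_in_every_dialect(self, dialect):
        assert render(parse_expression("alpha"), dialect) == "alpha"

    def test_power_renders_to_host_semantics(self):
        text = render(parse_expression("Pow(x, 2)"), PYTHON)
        assert eval(text, python_runtime_env(), {"x": 3.0}) == 9.0

    def test_unmapped_builtin_names_builtin_and_dialect(self):
        table = DialectTable(dialect_id="bare")
        with pytest.raises(RenderError, match="Sqrt.*bare"):
            render(parse_expression("Sqrt(2)"), table)

    def test_rendered_r_spellings(self):
        expr = parse_expression("Exp(1) + Ln(x)")
        assert render(expr, R) == "exp(1.0) + log(x)"
        assert render(expr, JULIA) == "exp(1.0) + log(x)"


class TestParseRenderRoundTrip:
    """Rendering to the common form and re-parsing preserves semantics."""

    def _envs(self, rng, idents, n=10):
        return [{name: float(rng.uniform(-3, 3)) for name in idents} for _ in range(n)]

    def test_agreement_on_random_expressions(self):
        rng = np.random.default_rng(7)
        idents = ["x", "y", "z"]
        py_globals = python_runtime_env()
        for _ in range(200):
            expr = random_expression(rng, idents, max_depth=4)
            reparsed = parse_expression(render(expr, PSEUDOCODE))
            py_text = render(expr, PYTHON)
            for env in self._envs(rng, idents):
                want = evaluate(expr, env)
                got = evaluate(reparsed, env)
                host = float(eval(py_text, py_globals, dict(env)))
                scale = max(1.0, abs(want))
                assert abs(got - want) <= 1e-12 * scale
                assert abs(host - want) <= 1e-12 * scale

    def test_render_is_canonical_fixpoint(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            expr = random_expression(rng, ["u", "v"], max_depth=4)
            once = render(expr, PSEUDOCODE)
            assert render(parse_expression(once), PSEUDOCODE) == once

    def test_fixed_seed_bit_reproducible(self):
        rng = np.random.default_rng(3)
        exprs_a = [random_expression(np.random.default_rng(99), ["x"], 4).source for _ in range(3)]
        exprs_b = [random_expression(np.random.default_rng(99), ["x"], 4).source for _ in range(3)]
        assert exprs_a[0] == exprs_b[0]
        expr = parse_expression("RandUnif() + RandUnif()")
        a = evaluate(expr, {}, rng=np.random.default_rng(5))
        b = evaluate(expr, {}, rng=np.random.default_rng(5))
        assert a == b
        del rng

    def test_rendered_r_evaluates_identically(self, tmp_path):
        # independent cross-language check of the R renderings via Rscript
        import subprocess

        rng = np.random.default_rng(13)
        exprs = [random_expression(rng, ["x", "y"], max_depth=3) for _ in range(20)]
        env = {"x": 1.25, "y": -0.75}
        lines = ["Step <- function(x) if (x >= 0) 1.0 else 0.0",
                 "x <- 1.25", "y <- -0.75"]
        for e in exprs:
            lines.append(f"cat(sprintf('%.17g', as.numeric({render(e, R)})), '\\n')")
        script = tmp_path / "check.R"
        script.write_text("\n".join(lines) + "\n")
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        got = [float(v) for v in out.stdout.split()]
        want = [evaluate(e, env) for e in exprs]
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)
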