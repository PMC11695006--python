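"""LaTeX report generation: equation pairing, tables, figures, escaping."""

import pytest

from mospec.companion import (
    COMPANION_DIALECT, CompanionError, equation_block, generate_companion,
    latex_escape, to_latex_math,
)
from mospec.expressions import parse_expression, render
from mospec.model import ParameterDef, VariableDef


def _verbatim_text(block: str) -> str:
    inner = block.split("\\begin{verbatim}")[1].split("\\end{verbatim}")[0]
    return inner.strip()


class TestEquationBlock:
    def test_state_variable_pairs_derivative_and_verbatim(self):
        v = VariableDef(name="X", kind="state", defining_expression="-k*X",
                        initial_condition="1", latex_name="X")
        block = equation_block(v, name_map={"X": "X", "k": "k"})
        assert "\\frac{d\\, X}{dt}" in block
        expected = render(parse_expression("-k*X"), COMPANION_DIALECT)
        assert _verbatim_text(block) == f"d_X = {expected}"

    def test_algebraic_variable_uses_plain_equality(self):
        v = VariableDef(name="A", kind="algebraic", defining_expression="B + 1")
        block = equation_block(v)
        assert "\\frac" not in block.split("\\begin{verbatim}")[0]
        assert _verbatim_text(block) == "A = B + 1.0"

    def test_latex_name_in_math_plain_name_in_verbatim(self):
        p = ParameterDef(name="b", kind="determined", defining_expression="2*a",
                         latex_name="\\beta")
        block = equation_block(p, name_map={"b": "\\beta", "a": "a"})
        math_half = block.split("\\begin{verbatim}")[0]
        assert "\\beta" in math_half
        verbatim = _verbatim_text(block)
        assert verbatim.startswith("b = ") and "\\beta" not in verbatim


class TestMathSynthesis:
    @pytest.mark.parametrize(
        "source,fragment",
        [
            ("a/b", "\\frac{a}{b}"),
            ("x^2", "{x}^{2}"),
            ("a*b", "a \\cdot b"),
            ("Exp(-k*t)", "e^{"),
            ("Sqrt(x)", "\\sqrt{x}"),
            ("Abs(x)", "\\left|x\\right|"),
            ("x <= 1", "\\leq"),
            ("x != 1", "\\neq"),
            ("Step(x)", "H\\!\\left(x\\right)"),
        ],
    )
    def test_fixed_mapping(self, source, fragment):
        tex = to_latex_math(parse_expression(source), {"a": "a", "b": "b", "x": "x", "k": "k"})
        assert fragment in tex

    def test_unmapped_identifier_falls_back_to_mathit(self):
        tex = to_latex_math(parse_expression("S_init + 1"), {})
        assert "\\mathit{S\\_init}" in tex


class TestEscaping:
    def test_special_characters_escaped(self):
        assert latex_escape("50% & $5 #1 _x {y} ~z") == (
            "50\\% \\& \\$5 \\#1 \\_x \\{y\\} \\textasciitilde{}z"
        )

    def test_description_text_escaped_in_tables(self, two_lovers, tmp_path):
        two_lovers.parameters[0].description = "rate in %/day & more"
        doc = generate_companion(two_lovers, tmp_path)
        table = doc.fragment_files["TwoLoversParametersTable.tex"]
        assert "rate in \\%/day \\& more" in table
        assert "%/day & more" not in table


class TestDocumentGeneration:
    def test_table_row_counts(self, two_lovers, tmp_path):
        doc = generate_companion(two_lovers, tmp_path)
        vt = doc.fragment_files["TwoLoversVariablesTable.tex"]
        pt = doc.fragment_files["TwoLoversParametersTable.tex"]
        assert vt.count("\\\\") - 1 == len(two_lovers.variables)  # minus header row
        assert pt.count("\\\\") - 1 == len(two_lovers.parameters)

    def test_every_name_appears_once_in_its_table(self, seir, tmp_path):
        doc = generate_companion(seir, tmp_path)
        pt = doc.fragment_files["SEIRParametersTable.tex"]
        for p in seir.parameters:
            prefix = latex_escape(p.name) + " &"
            rows = [line for line in pt.splitlines() if line.startswith(prefix)]
            assert len(rows) == 1

    def test_equation_blocks_cover_all_defined_quantities(self, seir, tmp_path):
        doc = generate_companion(seir, tmp_path)
        eq = doc.fragment_files["SEIREquations.tex"]
        count = len(seir.variables) + len(seir.determined_parameters)
        assert eq.count("\\begin{verbatim}") == count

    def test_fragments_input_exactly_once(self, toy, tmp_path):
        doc = generate_companion(toy, tmp_path, figure_dir=None)
        for frag in doc.fragment_files:
            stem = frag[: -len(".tex")]
            assert doc.main_file.count("\\input{" + stem + "}") == 1

    def test_no_figures_no_figure_environment(self, two_lovers, tmp_path):
        doc = generate_companion(two_lovers, tmp_path)
        assert "TwoLoversFigures.tex" not in doc.fragment_files
        assert "\\includegraphics" not in doc.main_file
        assert doc.referenced_figures == []

    def test_missing_figure_file_is_named(self, toy, tmp_path):
        with pytest.raises(CompanionError, match="toy_diagram.png"):
            generate_companion(toy, tmp_path / "out", figure_dir=tmp_path)

    def test_present_figure_is_included_in_order(self, toy, tmp_path):
        (tmp_path / "toy_diagram.png").write_bytes(b"\x89PNG\r\n")
        doc = generate_companion(toy, tmp_path / "out", figure_dir=tmp_path)
        figures = doc.fragment_files["ConstrainedToyFigures.tex"]
        assert "\\includegraphics[width=0.8\\linewidth]{toy_diagram.png}" in figures
        assert "\\label{fig:toy}" in figures

    def test_regeneration_is_byte_identical(self, seir, tmp_path):
        a = generate_companion(seir, tmp_path / "a")
        b = generate_companion(seir, tmp_path / "b")
        assert a.main_file == b.main_file
        assert a.fragment_files == b.fragment_files

    def test_files_written_to_disk(self, two_lovers, tmp_path):
        doc = generate_companion(two_lovers, tmp_path)
        main = tmp_path / "TwoLoversCompanion.tex"
        assert main.read_text() == doc.main_file
        assert "TwoLovers.MoSpec V02.04.03" in doc.main_file
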