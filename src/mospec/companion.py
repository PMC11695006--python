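"""Generation of the LaTeX model report ("Companion").

The report pairs, for every defined quantity, the mathematical form of its
right-hand side (synthesised from the parsed AST using the workbook's LaTeX
names) with the verbatim computational definition (the code generator's
rendering of the same AST), so a modeler can check by eye that the code
expresses exactly the intended equation.  It also carries auto-generated
variable/parameter tables, the constraint list with error codes, and any
figures declared in the LaTeX-controls sheet.

Description text is escaped; ``latex_name``/``latex_text`` fields are
trusted raw LaTeX, as they exist precisely to carry it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .dialects import PYTHON, DialectTable
from .expressions import (
    And, Bin, Call, Cmp, Expression, If, Neg, Node, Not, Num, Or, Ref, Time,
    parse_expression, render,
)
from .model import (
    ModelSpec, ParameterDef, VariableDef, version_string,
)

#: dialect whose rendering appears in the verbatim half of each equation
#: block — the host dialect, i.e. the code that actually runs here.
COMPANION_DIALECT = PYTHON


class CompanionError(ValueError):
    pass


@dataclass
class CompanionDocument:
    main_file: str
    fragment_files: dict[str, str] = field(default_factory=dict)
    referenced_figures: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# LaTeX text escaping

_ESCAPES = [
    ("\\", r"\textbackslash{}"),
    ("&", r"\&"),
    ("%", r"\%"),
    ("$", r"\$"),
    ("#", r"\#"),
    ("_", r"\_"),
    ("{", r"\{"),
    ("}", r"\}"),
    ("~", r"\textasciitilde{}"),
    ("^", r"\textasciicircum{}"),
]


def latex_escape(text: str) -> str:
    out = str(text)
    for raw, esc in _ESCAPES:
        out = out.replace(raw, esc)
    return out


# ---------------------------------------------------------------------------
# math synthesis from the AST

_CMP_TEX = {"<": "<", "<=": r"\leq", ">": ">", ">=": r"\geq", "==": "=", "!=": r"\neq"}
_FUNC_TEX = {
    "Ln": r"\ln", "Min": r"\min", "Max": r"\max",
    "Sin": r"\sin", "Cos": r"\cos",
}


def to_latex_math(expr: Expression, name_map: dict[str, str]) -> str:
    """Deterministic math-mode rendering of an expression.

    ``name_map`` maps identifiers to their LaTeX names; identifiers without
    an entry fall back to ``\\mathit{name}`` with underscores escaped.
    """
    return _tex(expr.root, name_map)


def _tex_name(name: str, name_map: dict[str, str]) -> str:
    mapped = name_map.get(name, "")
    if mapped:
        return mapped
    return r"\mathit{" + name.replace("_", r"\_") + "}"


def _needs_parens(node: Node) -> bool:
    return isinstance(node, (Bin, Cmp, And, Or, Not, Neg)) and not (
        isinstance(node, Bin) and node.op in ("/", "^")
    )


def _tex_wrap(node: Node, name_map) -> str:
    text = _tex(node, name_map)
    return r"\left(" + text + r"\right)" if _needs_parens(node) else text


def _tex(node: Node, nm: dict[str, str]) -> str:
    if isinstance(node, Num):
        v = node.value
        return str(int(v)) if v == int(v) and abs(v) < 1e15 else repr(v)
    if isinstance(node, Ref):
        return _tex_name(node.name, nm)
    if isinstance(node, Time):
        return "t"
    if isinstance(node, Neg):
        return "-" + _tex_wrap(node.operand, nm)
    if isinstance(node, Bin):
        if node.op == "/":
            return r"\frac{" + _tex(node.left, nm) + "}{" + _tex(node.right, nm) + "}"
        if node.op == "^":
            return "{" + _tex_wrap(node.left, nm) + "}^{" + _tex(node.right, nm) + "}"
        if node.op == "*":
            return _tex_wrap(node.left, nm) + r" \cdot " + _tex_wrap(node.right, nm)
        left, right = _tex(node.left, nm), _tex(node.right, nm)
        if isinstance(node.right, Neg) or (
            node.op == "-" and isinstance(node.right, Bin) and node.right.op in "+-"
        ):
            right = r"\left(" + right + r"\right)"
        return f"{left} {node.op} {right}"
    if isinstance(node, Cmp):
        return f"{_tex(node.left, nm)} {_CMP_TEX[node.op]} {_tex(node.right, nm)}"
    if isinstance(node, And):
        return _tex_wrap(node.left, nm) + r" \land " + _tex_wrap(node.right, nm)
    if isinstance(node, Or):
        return _tex_wrap(node.left, nm) + r" \lor " + _tex_wrap(node.right, nm)
    if isinstance(node, Not):
        return r"\lnot " + _tex_wrap(node.operand, nm)
    if isinstance(node, If):
        return (
            r"\begin{cases} "
            + _tex(node.then, nm) + " & " + _tex(node.cond, nm)
            + r" \\ "
            + _tex(node.otherwise, nm) + r" & \text{otherwise} \end{cases}"
        )
    if isinstance(node, Call):
        if node.name == "Exp":
            return r"e^{" + _tex(node.args[0], nm) + "}"
        if node.name == "Sqrt":
            return r"\sqrt{" + _tex(node.args[0], nm) + "}"
        if node.name == "Abs":
            return r"\left|" + _tex(node.args[0], nm) + r"\right|"
        if node.name == "Pow":
            return "{" + _tex_wrap(node.args[0], nm) + "}^{" + _tex(node.args[1], nm) + "}"
        if node.name == "Step":
            return r"H\!\left(" + _tex(node.args[0], nm) + r"\right)"
        if node.name == "RandUnif":
            return r"\mathcal{U}(0,1)"
        fn = _FUNC_TEX.get(node.name, r"\operatorname{" + node.name + "}")
        args = ", ".join(_tex(a, nm) for a in node.args)
        return fn + r"\left(" + args + r"\right)"
    raise CompanionError(f"unhandled node {node!r}")


# ---------------------------------------------------------------------------
# equation blocks


def _name_map(spec: ModelSpec) -> dict[str, str]:
    out = {}
    for v in spec.variables:
        if v.latex_name:
            out[v.name] = v.latex_name
    for p in spec.parameters:
        if p.latex_name:
            out[p.name] = p.latex_name
    return out


def equation_block(
    defn: VariableDef | ParameterDef,
    dialect: DialectTable = COMPANION_DIALECT,
    name_map: dict[str, str] | None = None,
) -> str:
    """One equation block: math form above, verbatim computational form below.

    State variables get derivative notation (dX/dt = ...); algebraic
    variables and determined parameters get plain equalities.  Both halves
    are derived from the same parsed AST; the verbatim half is exactly the
    code generator's rendering (`d_<name> = ...` for states, `<name> = ...`
    otherwise), which is the whole point: the document is the verification
    surface for the generated code.
    """
    name_map = name_map or {}
    expr = parse_expression(defn.defining_expression)
    lhs_tex = _tex_name(defn.name, name_map)
    if isinstance(defn, VariableDef) and defn.kind == "state":
        math_line = r"\frac{d\, " + lhs_tex + "}{dt} = " + to_latex_math(expr, name_map)
        verbatim_line = f"d_{defn.name} = {render(expr, dialect)}"
    else:
        math_line = lhs_tex + " = " + to_latex_math(expr, name_map)
        verbatim_line = f"{defn.name} = {render(expr, dialect)}"
    return "\n".join(
        [
            r"\begin{equation*}",
            math_line,
            r"\end{equation*}",
            r"\begin{verbatim}",
            verbatim_line,
            r"\end{verbatim}",
        ]
    )


# ---------------------------------------------------------------------------
# document generation


def _range_tex(lo, hi) -> str:
    lo_s = r"-\infty" if lo is None else _num_tex(lo)
    hi_s = r"+\infty" if hi is None else _num_tex(hi)
    return f"$[{lo_s}, {hi_s}]$"


def _num_tex(v: float) -> str:
    return str(int(v)) if v == int(v) and abs(v) < 1e15 else f"{v:g}"


def generate_companion(
    spec: ModelSpec, out_dir, figure_dir=None
) -> CompanionDocument:
    """Write the Companion LaTeX sources for ``spec`` under ``out_dir``.

    Emits ``<P>Companion.tex`` plus fragments (equations, variables table,
    parameters table, constraints, figures); each fragment is input exactly
    once by the main file.  When ``figure_dir`` is given, every declared
    figure file must exist there (:class:`CompanionError` naming the missing
    file otherwise).  Output is deterministic: regenerating from an
    unchanged spec is byte-identical.
    """
    P = spec.meta.project_name
    nm = _name_map(spec)
    figures = [f.file_name for f in spec.latex_controls.figure_entries]
    if figure_dir is not None:
        for fname in figures:
            if not os.path.exists(os.path.join(str(figure_dir), fname)):
                raise CompanionError(f"figure file '{fname}' not found in {figure_dir}")

    fragments: dict[str, str] = {}

    blocks = []
    for v in spec.variables:
        kind_note = "state variable" if v.kind == "state" else "algebraic variable"
        blocks.append(
            r"\subsection*{" + latex_escape(v.name) + f" ({kind_note})" + "}\n"
            + equation_block(v, COMPANION_DIALECT, nm)
        )
    for p in spec.determined_parameters:
        blocks.append(
            r"\subsection*{" + latex_escape(p.name) + " (determined parameter)}\n"
            + equation_block(p, COMPANION_DIALECT, nm)
        )
    fragments[f"{P}Equations.tex"] = (
        r"\section{Model equations}" + "\n\n" + "\n\n".join(blocks) + "\n"
    )

    lc = spec.latex_controls
    colspec = (
        f"p{{{lc.name_column_length}}}llp{{{lc.table_cell_length}}}ll"
    )
    rows = [
        r"\section{Variables}",
        r"\begin{tabular}{" + colspec + "}",
        r"Name & Symbol & Unit & Description & Range & Initial condition \\ \hline",
    ]
    for v in spec.variables:
        ic = r"\texttt{" + latex_escape(v.initial_condition) + "}" if v.initial_condition else "---"
        rows.append(
            " & ".join(
                [
                    latex_escape(v.name),
                    "$" + _tex_name(v.name, nm) + "$",
                    latex_escape(v.unit),
                    latex_escape(v.description),
                    _range_tex(v.range_min, v.range_max),
                    ic,
                ]
            )
            + r" \\"
        )
    rows.append(r"\end{tabular}")
    fragments[f"{P}VariablesTable.tex"] = "\n".join(rows) + "\n"

    rows = [
        r"\section{Parameters}",
        r"\begin{tabular}{" + colspec + "}",
        r"Name & Symbol & Unit & Description & Value & Kind \\ \hline",
    ]
    for p in spec.parameters:
        if p.kind == "free":
            value = "$" + _num_tex(p.reference_value) + "$" if p.reference_value is not None else "---"
            value += " " + _range_tex(p.min_admissible, p.max_admissible)
        else:
            value = r"\texttt{" + latex_escape(p.defining_expression or "") + "}"
        rows.append(
            " & ".join(
                [
                    latex_escape(p.name),
                    "$" + _tex_name(p.name, nm) + "$",
                    latex_escape(p.unit),
                    latex_escape(p.description),
                    value,
                    latex_escape(p.kind),
                ]
            )
            + r" \\"
        )
    rows.append(r"\end{tabular}")
    fragments[f"{P}ParametersTable.tex"] = "\n".join(rows) + "\n"

    rows = [r"\section{Constraints}"]
    if spec.constraints:
        rows.append(r"\begin{itemize}")
        for c in spec.constraints:
            text = c.latex_text or r"\texttt{" + latex_escape(c.predicate) + "}"
            rows.append(
                r"\item " + text + f" (error code {c.error_code}; "
                + r"predicate \texttt{" + latex_escape(c.predicate) + "})"
            )
        rows.append(r"\end{itemize}")
    else:
        rows.append("The model declares no parameter constraints.")
    fragments[f"{P}Constraints.tex"] = "\n".join(rows) + "\n"

    if figures:
        rows = [r"\section{Figures}"]
        for f in spec.latex_controls.figure_entries:
            rows += [
                r"\begin{figure}[ht]",
                r"\centering",
                r"\includegraphics[width=0.8\linewidth]{" + f.file_name + "}",
                r"\caption{" + latex_escape(f.caption) + "}",
                *( [r"\label{" + f.label + "}"] if f.label else [] ),
                r"\end{figure}",
            ]
        fragments[f"{P}Figures.tex"] = "\n".join(rows) + "\n"

    main_lines = [
        r"% Companion document for " + latex_escape(version_string(spec.meta)),
        r"\documentclass[11pt]{article}",
        r"\usepackage[T1]{fontenc}",
        r"\usepackage{amsmath}",
        r"\usepackage{graphicx}",
        r"\title{" + latex_escape(P) + r" --- Model Companion\\"
        + r"\large " + latex_escape(version_string(spec.meta)) + "}",
        r"\date{}",
        r"\begin{document}",
        r"\maketitle",
    ]
    if spec.notes:
        main_lines.append(latex_escape(spec.notes))
    for frag in fragments:
        main_lines.append(r"\input{" + frag[: -len(".tex")] + "}")
    main_lines.append(r"\end{document}")
    main_text = "\n".join(main_lines) + "\n"

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(str(out_dir), f"{P}Companion.tex"), "w", newline="\n") as fh:
        fh.write(main_text)
    for fname, text in fragments.items():
        with open(os.path.join(str(out_dir), fname), "w", newline="\n") as fh:
            fh.write(text)

    return CompanionDocument(
        main_file=main_text, fragment_files=fragments, referenced_figures=figures
    )
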