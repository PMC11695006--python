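"""Target-dialect tables: how pseudocode builtins and operators are spelled.

A :class:`DialectTable` carries everything the renderer needs to turn a parsed
pseudocode expression into source text for one target language: a function map
for named builtins and a small set of operator/templating conventions.  The
four workbook special-code sheets (C++, Matlab, R, Julia) override entries of
the shipped defaults; the host (python) table is built in and never read from
a workbook, mirroring a code generator whose own language needs no mapping
sheet.

Template placeholders: ``{l}``/``{r}`` for binary forms, ``{x}`` for unary,
``{cond}``/``{then}``/``{else}`` for the conditional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class DialectTable:
    """Rendering conventions for one target language."""

    dialect_id: str
    function_map: dict[str, str] = field(default_factory=dict)
    power_template: str = "({l})^({r})"
    and_template: str = "(({l}) and ({r}))"
    or_template: str = "(({l}) or ({r}))"
    not_template: str = "(not ({x}))"
    if_template: str = "If({cond}, {then}, {else})"
    eq_op: str = "=="
    ne_op: str = "!="
    assign_op: str = "="
    true_literal: str = "true"
    false_literal: str = "false"
    comment_prefix: str = "#"
    source_extension: str = ".txt"

    def with_overrides(self, entries: dict[str, str]) -> "DialectTable":
        """Return a copy with workbook-sheet entries merged in.

        Keys naming a pseudocode builtin extend/replace ``function_map``;
        the special keys ``^ and or not If == != assign true false comment
        extension`` set the corresponding convention.  Operator values may
        be either a plain spelling (``**``, ``&&``, ``!``) or a full
        template containing placeholders (``{l}``/``{r}``, ``{x}``,
        ``{cond}``/``{then}``/``{else}``), which is taken verbatim.
        """
        fmap = dict(self.function_map)
        table = replace(self, function_map=fmap)
        for key, value in entries.items():
            if key == "^":
                table.power_template = (
                    value if "{l}" in value else "({l})" + value + "({r})"
                )
            elif key == "and":
                table.and_template = (
                    value if "{l}" in value else "(({l}) " + value + " ({r}))"
                )
            elif key == "or":
                table.or_template = (
                    value if "{l}" in value else "(({l}) " + value + " ({r}))"
                )
            elif key == "not":
                table.not_template = (
                    value if "{x}" in value else "(" + value + "({x}))"
                )
            elif key == "If":
                table.if_template = value
            elif key == "comment":
                table.comment_prefix = value
            elif key == "extension":
                table.source_extension = value
            elif key == "==":
                table.eq_op = value
            elif key == "!=":
                table.ne_op = value
            elif key == "assign":
                table.assign_op = value
            elif key == "true":
                table.true_literal = value
            elif key == "false":
                table.false_literal = value
            else:
                fmap[key] = value
        return table


# The common pseudocode form itself: rendering with this table followed by
# re-parsing is the identity (up to insignificant parentheses).
PSEUDOCODE = DialectTable(
    dialect_id="pseudocode",
    function_map={},
    power_template="({l})^({r})",
    and_template="(({l}) and ({r}))",
    or_template="(({l}) or ({r}))",
    not_template="(not ({x}))",
    if_template="If({cond}, {then}, {else})",
)

# Host dialect: the language this engine itself runs in.  Logical forms are
# wrapped so that, embedded in arithmetic, they evaluate to exactly 1/0 as the
# in-process evaluator defines.
PYTHON = DialectTable(
    dialect_id="python",
    function_map={
        "Exp": "math.exp",
        "Ln": "math.log",
        "Sqrt": "math.sqrt",
        "Abs": "abs",
        "Min": "min",
        "Max": "max",
        "Sin": "math.sin",
        "Cos": "math.cos",
        "Step": "Step",
        "RandUnif": "RandUnif",
    },
    power_template="({l})**({r})",
    and_template="(bool({l}) and bool({r}))",
    or_template="(bool({l}) or bool({r}))",
    not_template="(not bool({x}))",
    if_template="(({then}) if ({cond}) else ({else}))",
    eq_op="==",
    ne_op="!=",
    assign_op="=",
    true_literal="True",
    false_literal="False",
    comment_prefix="#",
    source_extension=".py",
)

R = DialectTable(
    dialect_id="r",
    function_map={
        "Exp": "exp",
        "Ln": "log",
        "Sqrt": "sqrt",
        "Abs": "abs",
        "Min": "min",
        "Max": "max",
        "Sin": "sin",
        "Cos": "cos",
        "Step": "Step",
        "RandUnif": "RandUnif",
    },
    power_template="({l})^({r})",
    and_template="((({l}) != 0) & (({r}) != 0))",
    or_template="((({l}) != 0) | (({r}) != 0))",
    not_template="(!(({x}) != 0))",
    if_template="(if ({cond}) ({then}) else ({else}))",
    eq_op="==",
    ne_op="!=",
    assign_op="<-",
    true_literal="TRUE",
    false_literal="FALSE",
    comment_prefix="#",
    source_extension=".R",
)

JULIA = DialectTable(
    dialect_id="julia",
    function_map={
        "Exp": "exp",
        "Ln": "log",
        "Sqrt": "sqrt",
        "Abs": "abs",
        "Min": "min",
        "Max": "max",
        "Sin": "sin",
        "Cos": "cos",
        "Step": "Step",
        "RandUnif": "RandUnif",
    },
    power_template="({l})^({r})",
    and_template="((({l}) != 0) && (({r}) != 0))",
    or_template="((({l}) != 0) || (({r}) != 0))",
    not_template="(!(({x}) != 0))",
    if_template="((({cond}) != 0) ? ({then}) : ({else}))",
    eq_op="==",
    ne_op="!=",
    assign_op="=",
    true_literal="true",
    false_literal="false",
    comment_prefix="#",
    source_extension=".jl",
)

MATLAB = DialectTable(
    dialect_id="matlab",
    function_map={
        "Exp": "exp",
        "Ln": "log",
        "Sqrt": "sqrt",
        "Abs": "abs",
        "Min": "min",
        "Max": "max",
        "Sin": "sin",
        "Cos": "cos",
        "Step": "Step",
        "RandUnif": "Rand",
    },
    power_template="({l})^({r})",
    and_template="(({l}) && ({r}))",
    or_template="(({l}) || ({r}))",
    not_template="(~({x}))",
    if_template="IfElse({cond}, {then}, {else})",
    eq_op="==",
    ne_op="~=",
    assign_op="=",
    true_literal="true",
    false_literal="false",
    comment_prefix="%",
    source_extension=".m",
)

CPP = DialectTable(
    dialect_id="cpp",
    function_map={
        "Exp": "exp",
        "Ln": "log",
        "Sqrt": "sqrt",
        "Abs": "fabs",
        "Min": "fmin",
        "Max": "fmax",
        "Sin": "sin",
        "Cos": "cos",
        "Step": "Step",
        "RandUnif": "RandUnif",
    },
    power_template="pow({l}, {r})",
    and_template="(({l}) && ({r}))",
    or_template="(({l}) || ({r}))",
    not_template="(!({x}))",
    if_template="(({cond}) ? ({then}) : ({else}))",
    eq_op="==",
    ne_op="!=",
    assign_op="=",
    true_literal="true",
    false_literal="false",
    comment_prefix="//",
    source_extension=".cpp",
)

#: Dialect tables shipped with the package, keyed by dialect id.
DEFAULT_DIALECTS: dict[str, DialectTable] = {
    d.dialect_id: d for d in (PSEUDOCODE, PYTHON, R, JULIA, MATLAB, CPP)
}

#: Dialects backed by a workbook special-code sheet, in sheet order (7-10).
SHEET_DIALECT_IDS = ("cpp", "matlab", "r", "julia")

#: Dialects for which a runnable package can be emitted.
EMISSION_DIALECT_IDS = ("python", "r", "julia")
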