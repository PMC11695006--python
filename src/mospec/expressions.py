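"""The pseudocode expression language: parsing, evaluation and rendering.

Every defining formula in a model workbook — algebraic variables, state
derivatives, initial conditions, determined parameters, constraint predicates
— is written in one common pseudocode dialect and parsed here into a small
AST.  The same AST then serves three consumers: the numeric evaluator (the
simulation core), the per-dialect renderer (code generation), and the LaTeX
math synthesiser (the model report).

Grammar, fixed for this artifact: C-style infix arithmetic with ``^`` for
power (right-associative), unary minus, the comparisons ``< <= > >= == !=``
(``=`` is accepted as an alias of ``==``; chaining ``a < b < c`` is a syntax
error), keyword logicals ``and or not``, named builtins called with
parentheses, and a three-argument conditional ``If(cond, then, else)``.
Precedence, loosest to tightest: or, and, not, comparisons, ``+ -``,
``* /``, unary minus, ``^``.  Whitespace is insignificant.  The identifier
``t`` is reserved for simulation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Optional, Union

from .dialects import DialectTable

TIME_SYMBOL = "t"


class ExpressionSyntaxError(ValueError):
    """Raised on malformed pseudocode; carries the 0-based character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EvaluationError(ValueError):
    """Raised when a structurally valid expression cannot be evaluated."""


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Ref:
    name: str


@dataclass(frozen=True)
class Time:
    pass


@dataclass(frozen=True)
class Neg:
    operand: "Node"


@dataclass(frozen=True)
class Bin:
    op: str  # one of + - * / ^
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Cmp:
    op: str  # one of < <= > >= == !=
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Not:
    operand: "Node"


@dataclass(frozen=True)
class Call:
    name: str
    args: tuple["Node", ...]


@dataclass(frozen=True)
class If:
    cond: "Node"
    then: "Node"
    otherwise: "Node"


Node = Union[Num, Ref, Time, Neg, Bin, Cmp, And, Or, Not, Call, If]


@dataclass(frozen=True)
class Expression:
    """A parsed formula: the AST root plus its verbatim source text."""

    root: Node
    source: str

    def free_identifiers(self) -> set[str]:
        """Names referenced by this expression (the time symbol excluded)."""
        out: set[str] = set()
        _walk_refs(self.root, out)
        return out

    def function_names(self) -> set[str]:
        out: set[str] = set()
        _walk_calls(self.root, out)
        return out

    def references_time(self) -> bool:
        return _uses_time(self.root)


def _walk_refs(node: Node, out: set[str]) -> None:
    if isinstance(node, Ref):
        out.add(node.name)
    for child in _children(node):
        _walk_refs(child, out)


def _walk_calls(node: Node, out: set[str]) -> None:
    if isinstance(node, Call):
        out.add(node.name)
    for child in _children(node):
        _walk_calls(child, out)


def _uses_time(node: Node) -> bool:
    if isinstance(node, Time):
        return True
    return any(_uses_time(c) for c in _children(node))


def _children(node: Node) -> tuple[Node, ...]:
    if isinstance(node, (Num, Ref, Time)):
        return ()
    if isinstance(node, (Neg, Not)):
        return (node.operand,)
    if isinstance(node, (Bin, Cmp, And, Or)):
        return (node.left, node.right)
    if isinstance(node, Call):
        return node.args
    if isinstance(node, If):
        return (node.cond, node.then, node.otherwise)
    raise TypeError(f"unknown node {node!r}")


# ---------------------------------------------------------------------------
# Builtin registry

#: pseudocode builtin -> (arity, numeric implementation)
#: Implementations receive already-evaluated float arguments plus the rng.
BUILTINS: dict[str, tuple[int, Callable[..., float]]] = {
    "RandUnif": (0, lambda rng: float(rng.random())),
    "Exp": (1, lambda x, rng: math.exp(x)),
    "Ln": (1, lambda x, rng: _ln(x)),
    "Sqrt": (1, lambda x, rng: _sqrt(x)),
    "Abs": (1, lambda x, rng: abs(x)),
    "Min": (2, lambda a, b, rng: min(a, b)),
    "Max": (2, lambda a, b, rng: max(a, b)),
    "Pow": (2, lambda a, b, rng: float(a) ** float(b)),
    "Step": (1, lambda x, rng: 1.0 if x >= 0.0 else 0.0),
    "Sin": (1, lambda x, rng: math.sin(x)),
    "Cos": (1, lambda x, rng: math.cos(x)),
}

#: `If` is syntactically a call but becomes its own (lazily evaluated) node.
CONDITIONAL_NAME = "If"


def _ln(x: float) -> float:
    if x <= 0.0:
        raise EvaluationError(f"Ln of non-positive value {x}")
    return math.log(x)


def _sqrt(x: float) -> float:
    if x < 0.0:
        raise EvaluationError(f"Sqrt of negative value {x}")
    return math.sqrt(x)


# ---------------------------------------------------------------------------
# Tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # num | ident | op | end
    text: str
    pos: int


_TWO_CHAR_OPS = ("<=", ">=", "==", "!=")
_ONE_CHAR_OPS = "+-*/^()<>=,"


def _tokenize(source: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(source)
    while i < n:
        c = source[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and source[i + 1].isdigit()):
            j = i
            while j < n and (source[j].isdigit() or source[j] == "."):
                j += 1
            if j < n and source[j] in "eE":
                k = j + 1
                if k < n and source[k] in "+-":
                    k += 1
                if k < n and source[k].isdigit():
                    j = k
                    while j < n and source[j].isdigit():
                        j += 1
            text = source[i:j]
            try:
                float(text)
            except ValueError:
                raise ExpressionSyntaxError(f"malformed number {text!r}", i)
            tokens.append(_Token("num", text, i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            tokens.append(_Token("ident", source[i:j], i))
            i = j
            continue
        if source[i : i + 2] in _TWO_CHAR_OPS:
            tokens.append(_Token("op", source[i : i + 2], i))
            i += 2
            continue
        if c in _ONE_CHAR_OPS:
            tokens.append(_Token("op", c, i))
            i += 1
            continue
        raise ExpressionSyntaxError(f"unexpected character {c!r}", i)
    tokens.append(_Token("end", "", n))
    return tokens


# ---------------------------------------------------------------------------
# Parser (recursive descent)


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, text: str) -> None:
        if self.cur.kind == "op" and self.cur.text == text:
            self.advance()
            return
        raise ExpressionSyntaxError(
            f"expected {text!r}, found {self.cur.text or 'end of input'!r}",
            self.cur.pos,
        )

    def at_op(self, *texts: str) -> bool:
        return self.cur.kind == "op" and self.cur.text in texts

    def at_keyword(self, word: str) -> bool:
        return self.cur.kind == "ident" and self.cur.text == word

    # precedence ladder -----------------------------------------------------

    def parse(self) -> Node:
        node = self.or_expr()
        if self.cur.kind != "end":
            raise ExpressionSyntaxError(
                f"unexpected trailing input {self.cur.text!r}", self.cur.pos
            )
        return node

    def or_expr(self) -> Node:
        node = self.and_expr()
        while self.at_keyword("or"):
            self.advance()
            node = Or(node, self.and_expr())
        return node

    def and_expr(self) -> Node:
        node = self.not_expr()
        while self.at_keyword("and"):
            self.advance()
            node = And(node, self.not_expr())
        return node

    def not_expr(self) -> Node:
        if self.at_keyword("not"):
            self.advance()
            return Not(self.not_expr())
        return self.comparison()

    def comparison(self) -> Node:
        node = self.additive()
        if self.at_op("<", "<=", ">", ">=", "==", "!=", "="):
            op = self.advance().text
            if op == "=":
                op = "=="
            right = self.additive()
            if self.at_op("<", "<=", ">", ">=", "==", "!=", "="):
                raise ExpressionSyntaxError(
                    "comparison chaining is not allowed", self.cur.pos
                )
            return Cmp(op, node, right)
        return node

    def additive(self) -> Node:
        node = self.multiplicative()
        while self.at_op("+", "-"):
            op = self.advance().text
            node = Bin(op, node, self.multiplicative())
        return node

    def multiplicative(self) -> Node:
        node = self.unary()
        while self.at_op("*", "/"):
            op = self.advance().text
            node = Bin(op, node, self.unary())
        return node

    def unary(self) -> Node:
        if self.at_op("-"):
            self.advance()
            return Neg(self.unary())
        if self.at_op("+"):
            self.advance()
            return self.unary()
        return self.power()

    def power(self) -> Node:
        base = self.atom()
        if self.at_op("^"):
            self.advance()
            # right-associative; exponent may carry its own unary minus
            return Bin("^", base, self.unary())
        return base

    def atom(self) -> Node:
        tok = self.cur
        if tok.kind == "num":
            self.advance()
            return Num(float(tok.text))
        if tok.kind == "ident":
            self.advance()
            if self.at_op("("):
                return self.call(tok)
            if tok.text == TIME_SYMBOL:
                return Time()
            if tok.text in ("and", "or", "not"):
                raise ExpressionSyntaxError(
                    f"misplaced keyword {tok.text!r}", tok.pos
                )
            return Ref(tok.text)
        if self.at_op("("):
            self.advance()
            node = self.or_expr()
            self.expect_op(")")
            return node
        raise ExpressionSyntaxError(
            f"unexpected {tok.text or 'end of input'!r}", tok.pos
        )

    def call(self, name_tok: _Token) -> Node:
        self.expect_op("(")
        args: list[Node] = []
        if not self.at_op(")"):
            args.append(self.or_expr())
            while self.at_op(","):
                self.advance()
                args.append(self.or_expr())
        self.expect_op(")")
        if name_tok.text == CONDITIONAL_NAME:
            if len(args) != 3:
                raise ExpressionSyntaxError(
                    "If takes exactly (condition, then, else)", name_tok.pos
                )
            return If(args[0], args[1], args[2])
        return Call(name_tok.text, tuple(args))


def parse_expression(source: str) -> Expression:
    """Parse pseudocode text into an :class:`Expression`.

    Raises :class:`ExpressionSyntaxError` (with character position) on any
    malformed input, including empty source and unbalanced parentheses.
    """
    if source is None or not str(source).strip():
        raise ExpressionSyntaxError("empty expression", 0)
    source = str(source)
    return Expression(root=_Parser(source).parse(), source=source)


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(
    expr: Expression,
    env: dict[str, float],
    t: Optional[float] = None,
    rng=None,
) -> float:
    """Numerically evaluate ``expr``.

    ``env`` binds identifiers to numbers; ``t`` binds the time symbol (None
    means time may not be referenced).  Truth values are 1.0/0.0; the
    conditional evaluates only the taken branch; ``RandUnif`` draws from
    ``rng`` (a ``numpy.random.Generator`` or anything with ``.random()``),
    so results are deterministic under a fixed seed.
    """
    return _eval(expr.root, env, t, rng)


def _truthy(x: float) -> bool:
    return x != 0.0


def _eval(node: Node, env, t, rng) -> float:
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Ref):
        try:
            return float(env[node.name])
        except KeyError:
            raise EvaluationError(f"unbound identifier '{node.name}'")
    if isinstance(node, Time):
        if t is None:
            raise EvaluationError("time symbol 't' is not available here")
        return float(t)
    if isinstance(node, Neg):
        return -_eval(node.operand, env, t, rng)
    if isinstance(node, Bin):
        left = _eval(node.left, env, t, rng)
        right = _eval(node.right, env, t, rng)
        if node.op == "+":
            return left + right
        if node.op == "-":
            return left - right
        if node.op == "*":
            return left * right
        if node.op == "/":
            if right == 0.0:
                raise EvaluationError(f"division by zero in '{_repr_node(node)}'")
            return left / right
        if node.op == "^":
            try:
                return float(left**right)
            except (OverflowError, ValueError) as exc:
                raise EvaluationError(f"power error in '{_repr_node(node)}': {exc}")
        raise EvaluationError(f"unknown operator {node.op!r}")
    if isinstance(node, Cmp):
        left = _eval(node.left, env, t, rng)
        right = _eval(node.right, env, t, rng)
        result = {
            "<": left < right,
            "<=": left <= right,
            ">": left > right,
            ">=": left >= right,
            "==": left == right,
            "!=": left != right,
        }[node.op]
        return 1.0 if result else 0.0
    if isinstance(node, And):
        return (
            1.0
            if _truthy(_eval(node.left, env, t, rng))
            and _truthy(_eval(node.right, env, t, rng))
            else 0.0
        )
    if isinstance(node, Or):
        return (
            1.0
            if _truthy(_eval(node.left, env, t, rng))
            or _truthy(_eval(node.right, env, t, rng))
            else 0.0
        )
    if isinstance(node, Not):
        return 0.0 if _truthy(_eval(node.operand, env, t, rng)) else 1.0
    if isinstance(node, If):
        if _truthy(_eval(node.cond, env, t, rng)):
            return _eval(node.then, env, t, rng)
        return _eval(node.otherwise, env, t, rng)
    if isinstance(node, Call):
        if node.name not in BUILTINS:
            raise EvaluationError(f"unknown function '{node.name}'")
        arity, fn = BUILTINS[node.name]
        if len(node.args) != arity:
            raise EvaluationError(
                f"'{node.name}' takes {arity} argument(s), got {len(node.args)}"
            )
        if node.name == "RandUnif" and rng is None:
            raise EvaluationError("RandUnif requires a seeded random stream")
        args = [_eval(a, env, t, rng) for a in node.args]
        return float(fn(*args, rng))
    raise EvaluationError(f"unhandled node {node!r}")


def _repr_node(node: Node) -> str:
    from .dialects import PSEUDOCODE

    return _render(node, PSEUDOCODE)


# ---------------------------------------------------------------------------
# Rendering

# precedence levels used only for minimal-parenthesis composition of the
# plain infix operators; template-driven forms parenthesize themselves.
_PREC_CMP, _PREC_ADD, _PREC_MUL, _PREC_NEG, _PREC_ATOM = 4, 5, 6, 7, 9


class RenderError(ValueError):
    """A builtin has no mapping in the requested dialect."""


def render(expr: Expression, dialect: DialectTable) -> str:
    """Render ``expr`` as source text in ``dialect``.

    Parenthesisation preserves the AST's evaluation order exactly (so the
    emitted arithmetic performs the same floating-point operations in the
    same order as the in-process evaluator).
    """
    return _render(expr.root, dialect)


def _render(node: Node, d: DialectTable) -> str:
    text, _ = _render_prec(node, d)
    return text


def _render_prec(node: Node, d: DialectTable) -> tuple[str, int]:
    if isinstance(node, Num):
        v = node.value
        # negative literals start with a unary minus sign, so as operands
        # they bind like a negation, not like an atom
        prec = _PREC_NEG if v < 0 else _PREC_ATOM
        if v == int(v) and abs(v) < 1e15:
            return f"{int(v)}.0" if d.dialect_id != "pseudocode" else f"{int(v)}", prec
        return repr(v), prec
    if isinstance(node, Ref):
        return node.name, _PREC_ATOM
    if isinstance(node, Time):
        return TIME_SYMBOL, _PREC_ATOM
    if isinstance(node, Neg):
        text, prec = _render_prec(node.operand, d)
        if prec <= _PREC_NEG:
            text = f"({text})"
        return f"-{text}", _PREC_NEG
    if isinstance(node, Bin):
        if node.op == "^":
            left = _render(node.left, d)
            right = _render(node.right, d)
            return d.power_template.format(l=left, r=right), _PREC_ATOM
        prec = _PREC_ADD if node.op in "+-" else _PREC_MUL
        ltext, lprec = _render_prec(node.left, d)
        rtext, rprec = _render_prec(node.right, d)
        if lprec < prec:
            ltext = f"({ltext})"
        if rprec <= prec:
            rtext = f"({rtext})"
        return f"{ltext} {node.op} {rtext}", prec
    if isinstance(node, Cmp):
        op = {"==": d.eq_op, "!=": d.ne_op}.get(node.op, node.op)
        ltext, lprec = _render_prec(node.left, d)
        rtext, rprec = _render_prec(node.right, d)
        if lprec <= _PREC_CMP:
            ltext = f"({ltext})"
        if rprec <= _PREC_CMP:
            rtext = f"({rtext})"
        return f"{ltext} {op} {rtext}", _PREC_CMP
    if isinstance(node, And):
        return (
            d.and_template.format(l=_render(node.left, d), r=_render(node.right, d)),
            _PREC_ATOM,
        )
    if isinstance(node, Or):
        return (
            d.or_template.format(l=_render(node.left, d), r=_render(node.right, d)),
            _PREC_ATOM,
        )
    if isinstance(node, Not):
        return d.not_template.format(x=_render(node.operand, d)), _PREC_ATOM
    if isinstance(node, If):
        rendered = d.if_template.format(
            cond=_render(node.cond, d),
            then=_render(node.then, d),
            **{"else": _render(node.otherwise, d)},
        )
        return rendered, _PREC_ATOM
    if isinstance(node, Call):
        if node.name == "Pow":
            left = _render(node.args[0], d)
            right = _render(node.args[1], d)
            return d.power_template.format(l=left, r=right), _PREC_ATOM
        if d.dialect_id == "pseudocode":
            target = node.name
        else:
            target = d.function_map.get(node.name)
            if target is None:
                raise RenderError(
                    f"builtin '{node.name}' has no mapping in dialect "
                    f"'{d.dialect_id}'"
                )
        args = ", ".join(_render(a, d) for a in node.args)
        return f"{target}({args})", _PREC_ATOM
    raise RenderError(f"unhandled node {node!r}")


# ---------------------------------------------------------------------------
# Random expression generation (property testing / self-checks)

_SAFE_CALLS = ["Abs", "Min", "Max", "Step", "Sin", "Cos"]


def random_expression(rng, identifiers: list[str], max_depth: int = 5) -> Expression:
    """Generate a random well-formed expression over ``identifiers``.

    Restricted to numerically total constructs (no division, logs or free
    powers) so that any environment is a valid evaluation point; used by the
    parse/render/evaluate agreement self-checks.
    """
    root = _random_node(rng, identifiers, max_depth)
    from .dialects import PSEUDOCODE

    return Expression(root=root, source=_render(root, PSEUDOCODE))


def _random_node(rng, idents: list[str], depth: int) -> Node:
    if depth <= 0:
        if rng.random() < 0.5 and idents:
            return Ref(idents[int(rng.integers(len(idents)))])
        return Num(round(float(rng.uniform(-3, 3)), 3))
    choice = rng.random()
    sub = depth - 1
    if choice < 0.30:
        op = ["+", "-", "*"][int(rng.integers(3))]
        return Bin(op, _random_node(rng, idents, sub), _random_node(rng, idents, sub))
    if choice < 0.38:
        return Neg(_random_node(rng, idents, sub))
    if choice < 0.46:
        op = ["<", "<=", ">", ">=", "==", "!="][int(rng.integers(6))]
        return Cmp(op, _random_node(rng, idents, sub), _random_node(rng, idents, sub))
    if choice < 0.54:
        return And(_random_node(rng, idents, sub), _random_node(rng, idents, sub))
    if choice < 0.60:
        return Or(_random_node(rng, idents, sub), _random_node(rng, idents, sub))
    if choice < 0.66:
        return Not(_random_node(rng, idents, sub))
    if choice < 0.74:
        return If(
            _random_node(rng, idents, sub),
            _random_node(rng, idents, sub),
            _random_node(rng, idents, sub),
        )
    if choice < 0.82:
        return Bin("^", _random_node(rng, idents, sub), Num(float(rng.integers(2, 4))))
    if choice < 0.92:
        name = _SAFE_CALLS[int(rng.integers(len(_SAFE_CALLS)))]
        arity = BUILTINS[name][0]
        return Call(name, tuple(_random_node(rng, idents, sub) for _ in range(arity)))
    if idents:
        return Ref(idents[int(rng.integers(len(idents)))])
    return Num(round(float(rng.uniform(-3, 3)), 3))


def python_runtime_env() -> dict:
    """Globals under which host-dialect renderings evaluate with ``eval``.

    Mirrors the prelude emitted at the top of generated host-dialect model
    files (math module, Step, and a RandUnif placeholder that must be rebound
    to a seeded stream before use).
    """

    def Step(x: float) -> float:
        return 1.0 if x >= 0.0 else 0.0

    def RandUnif() -> float:
        raise RuntimeError("bind RandUnif to a seeded stream before use")

    return {"math": math, "Step": Step, "RandUnif": RandUnif, "bool": bool}
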