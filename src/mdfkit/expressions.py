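"""Arithmetic expression language used throughout model documents.

Parameter values, function-call arguments and output-port values are plain
strings in a small arithmetic language.  The grammar covers numbers
(integer, float, scientific), identifiers, the binary operators
``+ - * / % **``, unary minus, parentheses, the comparisons
``< <= > >= == !=`` (which evaluate to 0/1), call syntax ``f(a, b)`` and
element indexing ``x[i]``.

Precedence, loosest to tightest: comparisons, then ``+ -``, then
``* / %``, then unary minus, then ``**`` (right-associative).  Unary minus
binds looser than ``**``, so ``-2**2`` evaluates to ``-4``, matching the
convention of mainstream languages.

The value algebra is single-sorted numeric: comparisons yield 0/1 rather
than booleans, and there is no conditional operator — branching belongs to
the condition system, not to expressions.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Expression",
    "ExpressionError",
    "SyntaxErrorInfo",
    "ExpressionSyntaxError",
    "UnboundIdentifierError",
    "UnknownFunctionError",
    "ShapeMismatchError",
    "parse",
    "evaluate",
    "free_identifiers",
    "canonical_source",
]


class ExpressionError(Exception):
    """Base class for expression-language errors."""


class ExpressionSyntaxError(ExpressionError):
    """Source string does not conform to the grammar.

    ``offset`` is the 0-based character offset of the first offending
    position in the source string.
    """

    def __init__(self, message: str, offset: int, source: str = ""):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset
        self.source = source


# Back-compat alias used in some call sites.
SyntaxErrorInfo = ExpressionSyntaxError


class UnboundIdentifierError(ExpressionError):
    def __init__(self, name: str):
        super().__init__(f"unbound identifier: {name!r}")
        self.name = name


class UnknownFunctionError(ExpressionError):
    def __init__(self, name: str):
        super().__init__(f"unknown function: {name!r}")
        self.name = name


class ShapeMismatchError(ExpressionError):
    def __init__(self, op: str, shape_a, shape_b):
        super().__init__(
            f"shape mismatch for {op!r}: {tuple(shape_a)} vs {tuple(shape_b)}"
        )
        self.op = op
        self.shapes = (tuple(shape_a), tuple(shape_b))


# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    value: float | int


@dataclass(frozen=True)
class Name:
    id: str


@dataclass(frozen=True)
class Unary:
    op: str  # only "-"
    operand: "Ast"


@dataclass(frozen=True)
class Binary:
    op: str
    left: "Ast"
    right: "Ast"


@dataclass(frozen=True)
class Call:
    name: str
    args: tuple["Ast", ...]


@dataclass(frozen=True)
class Index:
    base: "Ast"
    index: "Ast"


Ast = Constant | Name | Unary | Binary | Call | Index


@dataclass(frozen=True)
class Expression:
    """A parsed expression: the original source plus its AST."""

    source: str
    ast: Ast = field(compare=False)

    def canonical(self) -> str:
        return canonical_source(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.source


# --------------------------------------------------------------------------
# Lexer
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>\*\*|<=|>=|==|!=|[+\-*/%<>()\[\],])
    """,
    re.VERBOSE,
)

_COMPARISONS = ("<", "<=", ">", ">=", "==", "!=")


@dataclass(frozen=True)
class _Token:
    kind: str  # "number" | "name" | "op" | "end"
    text: str
    offset: int


def _tokenize(source: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(source):
        m = _TOKEN_RE.match(source, pos)
        if m is None:
            raise ExpressionSyntaxError(
                f"unexpected character {source[pos]!r}", pos, source
            )
        kind = m.lastgroup
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), m.start()))
        pos = m.end()
    tokens.append(_Token("end", "", len(source)))
    return tokens


# --------------------------------------------------------------------------
# Parser (recursive descent, one token of lookahead)
# --------------------------------------------------------------------------

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
        else:
            raise ExpressionSyntaxError(
                f"expected {text!r}", self.cur.offset, self.source
            )

    def at_op(self, *texts: str) -> bool:
        return self.cur.kind == "op" and self.cur.text in texts

    def parse(self) -> Ast:
        node = self.comparison()
        if self.cur.kind != "end":
            raise ExpressionSyntaxError(
                f"unexpected token {self.cur.text!r}", self.cur.offset, self.source
            )
        return node

    def comparison(self) -> Ast:
        node = self.additive()
        while self.at_op(*_COMPARISONS):
            op = self.advance().text
            node = Binary(op, node, self.additive())
        return node

    def additive(self) -> Ast:
        node = self.term()
        while self.at_op("+", "-"):
            op = self.advance().text
            node = Binary(op, node, self.term())
        return node

    def term(self) -> Ast:
        node = self.unary()
        while self.at_op("*", "/", "%"):
            op = self.advance().text
            node = Binary(op, node, self.unary())
        return node

    def unary(self) -> Ast:
        if self.at_op("-"):
            self.advance()
            return Unary("-", self.unary())
        return self.power()

    def power(self) -> Ast:
        base = self.postfix()
        if self.at_op("**"):
            self.advance()
            # right-associative; the exponent may carry a unary minus
            return Binary("**", base, self.unary())
        return base

    def postfix(self) -> Ast:
        node = self.atom()
        while True:
            if self.at_op("("):
                if not isinstance(node, Name):
                    raise ExpressionSyntaxError(
                        "only identifiers are callable", self.cur.offset, self.source
                    )
                self.advance()
                args: list[Ast] = []
                if not self.at_op(")"):
                    args.append(self.comparison())
                    while self.at_op(","):
                        self.advance()
                        args.append(self.comparison())
                self.expect_op(")")
                node = Call(node.id, tuple(args))
            elif self.at_op("["):
                self.advance()
                idx = self.comparison()
                self.expect_op("]")
                node = Index(node, idx)
            else:
                return node

    def atom(self) -> Ast:
        tok = self.cur
        if tok.kind == "number":
            self.advance()
            text = tok.text
            if re.fullmatch(r"\d+", text):
                return Constant(int(text))
            return Constant(float(text))
        if tok.kind == "name":
            self.advance()
            return Name(tok.text)
        if self.at_op("("):
            self.advance()
            node = self.comparison()
            self.expect_op(")")
            return node
        raise ExpressionSyntaxError(
            "expected an expression"
            if tok.kind == "end"
            else f"unexpected token {tok.text!r}",
            tok.offset,
            self.source,
        )


@functools.lru_cache(maxsize=8192)
def parse(source: str) -> Expression:
    """Parse ``source`` into an :class:`Expression`.

    Raises :class:`ExpressionSyntaxError` with a 0-based character offset on
    malformed input.  Results are cached: expressions are parsed once per
    distinct source string per process.
    """
    if not isinstance(source, str):
        raise TypeError(f"expression source must be a string, got {type(source)}")
    return Expression(source=source, ast=_Parser(source).parse())


# --------------------------------------------------------------------------
# Canonical rendering
# --------------------------------------------------------------------------

def _render(node: Ast) -> str:
    if isinstance(node, Constant):
        return repr(node.value)
    if isinstance(node, Name):
        return node.id
    if isinstance(node, Unary):
        return f"(-{_render(node.operand)})"
    if isinstance(node, Binary):
        return f"({_render(node.left)} {node.op} {_render(node.right)})"
    if isinstance(node, Call):
        return f"{node.name}({', '.join(_render(a) for a in node.args)})"
    if isinstance(node, Index):
        return f"{_render(node.base)}[{_render(node.index)}]"
    raise TypeError(f"not an AST node: {node!r}")  # pragma: no cover


def canonical_source(expr: Expression | str) -> str:
    """A fully parenthesized rendering that re-parses to the same AST."""
    if isinstance(expr, str):
        expr = parse(expr)
    return _render(expr.ast)


# --------------------------------------------------------------------------
# Free identifiers
# --------------------------------------------------------------------------

def _walk(node: Ast) -> Iterator[Ast]:
    yield node
    if isinstance(node, Unary):
        yield from _walk(node.operand)
    elif isinstance(node, Binary):
        yield from _walk(node.left)
        yield from _walk(node.right)
    elif isinstance(node, Call):
        for a in node.args:
            yield from _walk(a)
    elif isinstance(node, Index):
        yield from _walk(node.base)
        yield from _walk(node.index)


def free_identifiers(expr: Expression | str) -> list[str]:
    """Identifiers referenced by ``expr`` in first-appearance order.

    Call names are not identifiers (they resolve in the function ontology,
    not in the value environment).
    """
    if isinstance(expr, str):
        expr = parse(expr)
    seen: dict[str, None] = {}
    for node in _walk(expr.ast):
        if isinstance(node, Name):
            seen.setdefault(node.id, None)
    return list(seen)


def called_functions(expr: Expression | str) -> list[str]:
    """Function names called by ``expr`` in first-appearance order."""
    if isinstance(expr, str):
        expr = parse(expr)
    seen: dict[str, None] = {}
    for node in _walk(expr.ast):
        if isinstance(node, Call):
            seen.setdefault(node.name, None)
    return list(seen)


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def _binop(op: str, a, b, on_warning: Callable[[str], None] | None):
    aa, bb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if aa.ndim > 0 and bb.ndim > 0 and aa.shape != bb.shape:
        raise ShapeMismatchError(op, aa.shape, bb.shape)
    with np.errstate(all="ignore"):
        if op == "+":
            out = aa + bb
        elif op == "-":
            out = aa - bb
        elif op == "*":
            out = aa * bb
        elif op == "/":
            if on_warning is not None and np.any(bb == 0):
                on_warning("division_by_zero")
            out = aa / bb
        elif op == "%":
            if on_warning is not None and np.any(bb == 0):
                on_warning("division_by_zero")
            out = np.mod(aa, bb)
        elif op == "**":
            out = aa ** bb
        elif op in _COMPARISONS:
            cmp = {
                "<": np.less, "<=": np.less_equal,
                ">": np.greater, ">=": np.greater_equal,
                "==": np.equal, "!=": np.not_equal,
            }[op]
            out = cmp(aa, bb).astype(float)
        else:  # pragma: no cover - parser admits no other op
            raise ValueError(f"unknown operator {op!r}")
    return out


def _as_result(x):
    arr = np.asarray(x)
    if arr.ndim == 0:
        return float(arr)
    return arr


def evaluate(
    expr: Expression | str,
    bindings: Mapping[str, object] | None = None,
    functions=None,
    *,
    on_warning: Callable[[str], None] | None = None,
    rng=None,
):
    """Evaluate ``expr`` under ``bindings`` with functions from ``functions``.

    Scalars broadcast against arrays; array-array operands must agree in
    shape exactly.  Division by zero follows IEEE semantics (``inf``/``nan``)
    and reports through ``on_warning`` rather than raising.  ``rng`` is
    forwarded to stochastic ontology functions.
    """
    if isinstance(expr, str):
        expr = parse(expr)
    bindings = bindings or {}

    def ev(node: Ast):
        if isinstance(node, Constant):
            return node.value
        if isinstance(node, Name):
            try:
                return bindings[node.id]
            except KeyError:
                raise UnboundIdentifierError(node.id) from None
        if isinstance(node, Unary):
            return _as_result(-np.asarray(ev(node.operand), dtype=float))
        if isinstance(node, Binary):
            return _as_result(_binop(node.op, ev(node.left), ev(node.right), on_warning))
        if isinstance(node, Call):
            if functions is None:
                raise UnknownFunctionError(node.name)
            args = [ev(a) for a in node.args]
            return functions.call(node.name, args, rng=rng)
        if isinstance(node, Index):
            base = np.asarray(ev(node.base))
            idx = int(round(float(np.asarray(ev(node.index)))))
            try:
                return _as_result(base[idx])
            except IndexError:
                raise ExpressionError(
                    f"index {idx} out of bounds for shape {base.shape}"
                ) from None
        raise TypeError(f"not an AST node: {node!r}")  # pragma: no cover

    return ev(expr.ast)
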