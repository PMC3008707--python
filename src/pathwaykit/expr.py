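"""Rate-law mathematics: a small arithmetic expression tree.

Kinetic rate laws are stored as expression trees over numeric literals,
named references (species or parameters) and the binary operators
``+ - * / ^`` plus unary minus.  The deliberately bounded grammar keeps
every expression evaluatable, serialisable to SBML MathML (via libsbml)
and fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

__all__ = [
    "MathExpression",
    "Num",
    "Name",
    "BinOp",
    "Neg",
    "parse_expression",
    "ExpressionError",
]


class ExpressionError(ValueError):
    """Raised for parse failures, unbound names and domain errors."""


@dataclass(frozen=True)
class Num:
    value: float

    def __str__(self) -> str:
        v = self.value
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)


@dataclass(frozen=True)
class Name:
    ident: str

    def __str__(self) -> str:
        return self.ident


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * / ^
    left: "MathExpression"
    right: "MathExpression"

    def __str__(self) -> str:
        return f"({self.left} {self.op} {self.right})"


@dataclass(frozen=True)
class Neg:
    operand: "MathExpression"

    def __str__(self) -> str:
        return f"(-{self.operand})"


MathExpression = Union[Num, Name, BinOp, Neg]


def names_in(expr: MathExpression) -> set[str]:
    """All named references occurring in *expr*."""
    if isinstance(expr, Num):
        return set()
    if isinstance(expr, Name):
        return {expr.ident}
    if isinstance(expr, Neg):
        return names_in(expr.operand)
    return names_in(expr.left) | names_in(expr.right)


def substitute(expr: MathExpression, mapping: Mapping[str, str]) -> MathExpression:
    """Rename identifiers; names absent from *mapping* are kept as-is."""
    if isinstance(expr, Num):
        return expr
    if isinstance(expr, Name):
        return Name(mapping.get(expr.ident, expr.ident))
    if isinstance(expr, Neg):
        return Neg(substitute(expr.operand, mapping))
    return BinOp(expr.op, substitute(expr.left, mapping), substitute(expr.right, mapping))


def evaluate(expr: MathExpression, bindings: Mapping[str, float]) -> float:
    """Evaluate with standard arithmetic semantics.

    Raises :class:`ExpressionError` for an unbound name or division by zero.
    """
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Name):
        try:
            return float(bindings[expr.ident])
        except KeyError:
            raise ExpressionError(f"unbound name {expr.ident!r}") from None
    if isinstance(expr, Neg):
        return -evaluate(expr.operand, bindings)
    a = evaluate(expr.left, bindings)
    b = evaluate(expr.right, bindings)
    if expr.op == "+":
        return a + b
    if expr.op == "-":
        return a - b
    if expr.op == "*":
        return a * b
    if expr.op == "/":
        if b == 0:
            raise ExpressionError("division by zero")
        return a / b
    if expr.op == "^":
        if a < 0 and b != int(b):
            raise ExpressionError("fractional power of a negative base")
        try:
            return a ** b
        except (ZeroDivisionError, OverflowError) as e:
            raise ExpressionError(str(e)) from None
    raise ExpressionError(f"unknown operator {expr.op!r}")  # pragma: no cover


# --- infix parser (recursive descent) ---------------------------------------
#
# grammar:  expr   := term (('+'|'-') term)*
#           term   := factor (('*'|'/') factor)*
#           factor := '-' factor | power
#           power  := atom ('^' factor)?          (right associative)
#           atom   := NUMBER | NAME | '(' expr ')'
#
# NAME tokens may contain letters, digits, '_' and ':' so that database
# accessions such as CHEBI:4167 can appear directly in store rate laws.

_NAME_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_:")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "+-*/^()":
            tokens.append(ch)
            i += 1
        elif ch.isdigit() or ch == ".":
            j = i
            while j < n and (text[j].isdigit() or text[j] in ".eE" or
                             (text[j] in "+-" and j > i and text[j - 1] in "eE")):
                j += 1
            tokens.append(text[i:j])
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < n and text[j] in _NAME_CHARS:
                j += 1
            tokens.append(text[i:j])
            i = j
        else:
            raise ExpressionError(f"unexpected character {ch!r} at position {i}")
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> MathExpression:
        e = self.expr()
        if self.peek() is not None:
            raise ExpressionError(f"trailing input at token {self.peek()!r}")
        return e

    def expr(self) -> MathExpression:
        e = self.term()
        while self.peek() in ("+", "-"):
            op = self.take()
            e = BinOp(op, e, self.term())
        return e

    def term(self) -> MathExpression:
        e = self.factor()
        while self.peek() in ("*", "/"):
            op = self.take()
            e = BinOp(op, e, self.factor())
        return e

    def factor(self) -> MathExpression:
        if self.peek() == "-":
            self.take()
            return Neg(self.factor())
        return self.power()

    def power(self) -> MathExpression:
        base = self.atom()
        if self.peek() == "^":
            self.take()
            return BinOp("^", base, self.factor())
        return base

    def atom(self) -> MathExpression:
        tok = self.take()
        if tok == "(":
            e = self.expr()
            if self.take() != ")":
                raise ExpressionError("expected ')'")
            return e
        if tok[0].isdigit() or tok[0] == ".":
            try:
                return Num(float(tok))
            except ValueError:
                raise ExpressionError(f"bad number {tok!r}") from None
        if tok[0].isalpha() or tok[0] == "_":
            return Name(tok)
        raise ExpressionError(f"unexpected token {tok!r}")


def parse_expression(text: str) -> MathExpression:
    """Parse an infix rate-law string into an expression tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    return _Parser(tokens).parse()


def to_infix(expr: MathExpression) -> str:
    """Fully parenthesised infix rendering (round-trips through the parser)."""
    return str(expr)
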