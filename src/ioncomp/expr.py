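"""Arithmetic expression AST and operations on it.

Expressions are the right-hand sides of every equation in the language:
numbers (optionally unit-annotated), symbols, unary minus, the binary
operators ``+ - * / ^`` and function application.  Application is accepted
both in prefix form ``(exp x)`` and in juxtaposed form ``exp(x)``, as both
appear in idiomatic model listings.

The membrane potential may be written ``V`` or ``v`` in source; it is
normalized to ``v`` here so that every later stage sees a single spelling.

Runtime semantics follow IEEE doubles: division by zero and exp overflow
produce infinities/NaN rather than raising, matching the behaviour of the
numeric platforms the compiler targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

from .errors import EvaluationError, GrammarError
from .sexpr import Num, Op, SList, Sym, SyntaxNode, format_number, parse_sexpr

__all__ = [
    "Expr", "Neg", "Binary", "Apply", "Num", "Sym",
    "parse_expr", "parse_expr_items", "free_vars", "eval_expr", "subst",
    "write_expr", "BUILTIN_FUNCTIONS",
]


@dataclass(frozen=True)
class Neg:
    arg: "Expr"


@dataclass(frozen=True)
class Binary:
    op: str  # one of + - * / ^
    lhs: "Expr"
    rhs: "Expr"


@dataclass(frozen=True)
class Apply:
    relation: str
    args: Tuple["Expr", ...]


Expr = object  # Num | Sym | Neg | Binary | Apply


def _safe_div(a: float, b: float) -> float:
    try:
        return a / b
    except ZeroDivisionError:
        if a == 0 or a != a:
            return float("nan")
        return math.copysign(float("inf"), a) * math.copysign(1.0, b)


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return float("inf")


def _safe_pow(a: float, b: float) -> float:
    try:
        return math.pow(a, b)
    except (OverflowError, ValueError):
        return float("nan")


def _safe_log(x: float) -> float:
    if x < 0:
        return float("nan")
    if x == 0:
        return float("-inf")
    return math.log(x)


# name -> (arity, implementation); `ghk` is registered by ioncomp.ghk on
# import to avoid a circular dependency.
BUILTIN_FUNCTIONS = {
    "exp": (1, _safe_exp),
    "log": (1, _safe_log),
    "ln": (1, _safe_log),
    "log10": (1, lambda x: _safe_log(x) / math.log(10)),
    "sqrt": (1, lambda x: math.sqrt(x) if x >= 0 else float("nan")),
    "sin": (1, math.sin),
    "cos": (1, math.cos),
    "tan": (1, math.tan),
    "sinh": (1, math.sinh),
    "cosh": (1, math.cosh),
    "tanh": (1, math.tanh),
    "fabs": (1, math.fabs),
    "abs": (1, math.fabs),
    "pow": (2, _safe_pow),
}

_RESERVED_SPELLINGS = {"V": "v"}


def _norm(name: str) -> str:
    return _RESERVED_SPELLINGS.get(name, name)


# ---------------------------------------------------------------------------
# Parsing (Pratt parser over a list of syntax items)
# ---------------------------------------------------------------------------

_BIN_PREC = {"+": 10, "-": 10, "*": 20, "/": 20, "^": 30}
_UNARY_PREC = 25


class _ItemStream:
    def __init__(self, items):
        self.items = list(items)
        self.pos = 0

    def peek(self):
        return self.items[self.pos] if self.pos < len(self.items) else None

    def next(self):
        item = self.peek()
        if item is None:
            raise GrammarError("unexpected end of expression")
        self.pos += 1
        return item


def _is_prefix_application(node: SList) -> bool:
    # (f a b) is an application; any top-level operator makes it infix
    return (len(node) >= 2
            and isinstance(node[0], Sym)
            and not any(isinstance(x, Op) for x in node.items))


def _parse_item(item: SyntaxNode) -> Expr:
    """Parse one syntax item standing on its own as an expression."""
    if isinstance(item, Num):
        return item
    if isinstance(item, Sym):
        return Sym(_norm(item.name))
    if isinstance(item, SList):
        if _is_prefix_application(item):
            head = item[0].name
            return Apply(_norm(head) if head == "V" else head,
                         tuple(_parse_item(a) for a in item[1:]))
        return parse_expr_items(item.items)
    raise GrammarError(f"operator {item.name!r} cannot stand alone as an expression")


def _parse_primary(s: _ItemStream) -> Expr:
    item = s.next()
    if isinstance(item, Op):
        if item.name == "-":
            return Neg(_parse_binary(s, _UNARY_PREC))
        if item.name == "+":
            return _parse_binary(s, _UNARY_PREC)
        raise GrammarError(f"unexpected operator {item.name!r} in expression")
    if isinstance(item, Num):
        # a symbol juxtaposed to a number is a unit annotation
        nxt = s.peek()
        if item.unit is None and isinstance(nxt, Sym):
            s.next()
            return Num(item.value, nxt.name)
        return item
    if isinstance(item, Sym):
        nxt = s.peek()
        if isinstance(nxt, SList):  # juxtaposed application: exp(-V/80)
            s.next()
            try:
                args = (parse_expr_items(nxt.items),)
            except GrammarError:
                # several juxtaposed arguments: f(a b) / comma-stripped input
                args = tuple(_parse_item(a) for a in nxt.items)
            return Apply(item.name, args)
        return Sym(_norm(item.name))
    return _parse_item(item)


def _parse_binary(s: _ItemStream, min_prec: int) -> Expr:
    lhs = _parse_primary(s)
    while True:
        item = s.peek()
        if not isinstance(item, Op) or item.name not in _BIN_PREC:
            return lhs
        prec = _BIN_PREC[item.name]
        if prec < min_prec:
            return lhs
        s.next()
        # ^ is right-associative; the rest left-associative
        rhs = _parse_binary(s, prec if item.name == "^" else prec + 1)
        lhs = Binary(item.name, lhs, rhs)


def parse_expr_items(items) -> Expr:
    """Parse a sequence of syntax items (the tail of a form) as one expression."""
    s = _ItemStream(items)
    e = _parse_binary(s, 0)
    if s.peek() is not None:
        raise GrammarError(f"trailing tokens in expression: {s.peek()!r}")
    return e


def parse_expr(text: str) -> Expr:
    """Parse an expression written in the surface syntax."""
    node = parse_sexpr(f"({text})")
    return parse_expr_items(node.items)


# ---------------------------------------------------------------------------
# Free variables, evaluation, substitution
# ---------------------------------------------------------------------------

def free_vars(e: Expr) -> frozenset:
    """Identifiers occurring free in *e*.

    Applied relation names are included (they are dependencies for ordering);
    built-in function names are not.
    """
    if isinstance(e, Num):
        return frozenset()
    if isinstance(e, Sym):
        return frozenset((e.name,))
    if isinstance(e, Neg):
        return free_vars(e.arg)
    if isinstance(e, Binary):
        return free_vars(e.lhs) | free_vars(e.rhs)
    if isinstance(e, Apply):
        out = frozenset() if e.relation in BUILTIN_FUNCTIONS else frozenset((e.relation,))
        for a in e.args:
            out |= free_vars(a)
        return out
    raise TypeError(f"not an expression: {e!r}")


def eval_expr(e: Expr, bindings: Mapping, relations: Optional[Mapping] = None) -> float:
    """IEEE-double evaluation of *e* under *bindings*.

    ``relations`` maps names to RELATION entities (see
    :mod:`ioncomp.entities`); built-in functions are always available.
    """
    if isinstance(e, Num):
        return e.value
    if isinstance(e, Sym):
        try:
            return bindings[e.name]
        except KeyError:
            raise EvaluationError(f"unbound symbol {e.name!r}") from None
    if isinstance(e, Neg):
        return -eval_expr(e.arg, bindings, relations)
    if isinstance(e, Binary):
        a = eval_expr(e.lhs, bindings, relations)
        b = eval_expr(e.rhs, bindings, relations)
        if e.op == "+":
            return a + b
        if e.op == "-":
            return a - b
        if e.op == "*":
            return a * b
        if e.op == "/":
            return _safe_div(a, b)
        return _safe_pow(a, b)
    if isinstance(e, Apply):
        args = [eval_expr(a, bindings, relations) for a in e.args]
        builtin = BUILTIN_FUNCTIONS.get(e.relation)
        if builtin is not None:
            arity, fn = builtin
            if len(args) != arity:
                raise EvaluationError(
                    f"{e.relation} expects {arity} argument(s), got {len(args)}")
            return fn(*args)
        rel = (relations or {}).get(e.relation)
        if rel is None:
            raise EvaluationError(f"unknown relation {e.relation!r}")
        if len(args) != len(rel.formals):
            raise EvaluationError(
                f"relation {e.relation} expects {len(rel.formals)} argument(s), "
                f"got {len(args)}")
        inner = dict(bindings)
        inner.update(zip(rel.formals, args))
        return eval_expr(rel.rhs, inner, relations)
    raise TypeError(f"not an expression: {e!r}")


def subst(e: Expr, s: Mapping, shadow: frozenset = frozenset()) -> Expr:
    """Replace free occurrences of mapped identifiers by their expressions.

    *s* may be a chained mapping (e.g. ``collections.ChainMap``), in which
    case an identifier missing from the innermost environment is looked up in
    the enclosing ones.  Identifiers absent from every environment pass
    through unchanged.  Names in *shadow* (relation formals) are never
    substituted.
    """
    if isinstance(e, Num):
        return e
    if isinstance(e, Sym):
        if e.name in shadow:
            return e
        return s.get(e.name, e)
    if isinstance(e, Neg):
        return Neg(subst(e.arg, s, shadow))
    if isinstance(e, Binary):
        return Binary(e.op, subst(e.lhs, s, shadow), subst(e.rhs, s, shadow))
    if isinstance(e, Apply):
        name = e.relation
        if name not in BUILTIN_FUNCTIONS and name not in shadow:
            mapped = s.get(name)
            if isinstance(mapped, Sym):
                name = mapped.name
        return Apply(name, tuple(subst(a, s, shadow) for a in e.args))
    raise TypeError(f"not an expression: {e!r}")


def write_expr(e: Expr) -> str:
    """Canonical surface-syntax rendering (fully parenthesized infix)."""
    if isinstance(e, Num):
        s = format_number(e.value)
        return f"{s} {e.unit}" if e.unit else s
    if isinstance(e, Sym):
        return e.name
    if isinstance(e, Neg):
        return f"(- {write_expr(e.arg)})"
    if isinstance(e, Binary):
        return f"({write_expr(e.lhs)} {e.op} {write_expr(e.rhs)})"
    if isinstance(e, Apply):
        return "(" + " ".join([e.relation] + [write_expr(a) for a in e.args]) + ")"
    raise TypeError(f"not an expression: {e!r}")
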