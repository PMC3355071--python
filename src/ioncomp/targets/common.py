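"""Shared expression-to-code rendering for the code generation targets."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from ..entities import Entity
from ..expr import Apply, Binary, Expr, Neg, Num, Sym, free_vars
from ..odesystem import OdeSystem
from ..sexpr import format_number

__all__ = ["expr_to_code", "def_closure", "uses_ghk"]

# built-in function spellings per target language
_FN = {
    "python": {"ln": "_log", "log": "_log", "exp": "_exp", "abs": "fabs",
               "pow": "_pow"},
    "octave": {"ln": "log", "fabs": "abs"},
    "nmodl": {"ln": "log", "abs": "fabs"},
}


def _int_power(base: str, n: int) -> str:
    return "(" + " * ".join([base] * n) + ")"


def expr_to_code(e: Expr, lang: str,
                 rename: Optional[Dict[str, str]] = None) -> str:
    """Render *e* in the concrete syntax of *lang* (python/octave/nmodl)."""
    rename = rename or {}

    def go(e: Expr) -> str:
        if isinstance(e, Num):
            return format_number(e.value)
        if isinstance(e, Sym):
            return rename.get(e.name, e.name)
        if isinstance(e, Neg):
            return f"(-{go(e.arg)})"
        if isinstance(e, Binary):
            a, b = go(e.lhs), go(e.rhs)
            if e.op == "^":
                if (lang == "nmodl" and isinstance(e.rhs, Num)
                        and e.rhs.value == int(e.rhs.value)
                        and 1 <= e.rhs.value <= 8):
                    return _int_power(a, int(e.rhs.value))
                if lang == "python":
                    return f"_pow({a}, {b})"
                return f"({a} ^ {b})"
            if e.op == "/" and lang == "python":
                return f"_div({a}, {b})"
            return f"({a} {e.op} {b})"
        if isinstance(e, Apply):
            name = _FN.get(lang, {}).get(e.relation, e.relation)
            name = rename.get(name, name)
            return name + "(" + ", ".join(go(a) for a in e.args) + ")"
        raise TypeError(f"not an expression: {e!r}")

    return go(e)


def def_closure(sys: OdeSystem, roots: Iterable[str]
                ) -> Tuple[List[Tuple[str, str, Expr]], List[Entity], Set[str]]:
    """Defs (in system order) and relations reachable from *roots*.

    Returns (defs, relations, all reachable names incl. states/globals).
    """
    defs_map = {name: (kind, expr) for name, kind, expr in sys.defs}
    rel_map = sys.relations_map()
    needed: Set[str] = set()
    stack = list(roots)
    while stack:
        name = stack.pop()
        if name in needed:
            continue
        needed.add(name)
        if name in defs_map:
            stack.extend(free_vars(defs_map[name][1]))
        elif name in rel_map:
            rel = rel_map[name]
            stack.extend(free_vars(rel.rhs) - set(rel.formals))
    defs = [(n, k, e) for n, k, e in sys.defs if n in needed]
    relations = [r for r in sys.relations if r.name in needed]
    return defs, relations, needed


def split_state_dependent(defs, states: Set[str]):
    """Split topologically ordered defs into state-independent and
    (transitively) state-dependent groups, preserving order."""
    dep: Set[str] = set()
    pre, post = [], []
    for name, kind, e in defs:
        fv = free_vars(e)
        if (fv & states) or (fv & dep):
            dep.add(name)
            post.append((name, kind, e))
        else:
            pre.append((name, kind, e))
    return pre, post


def uses_ghk(exprs: Sequence[Expr]) -> bool:
    def walk(e) -> bool:
        if isinstance(e, Apply):
            return e.relation == "ghk" or any(walk(a) for a in e.args)
        if isinstance(e, Binary):
            return walk(e.lhs) or walk(e.rhs)
        if isinstance(e, Neg):
            return walk(e.arg)
        return False
    return any(walk(e) for e in exprs)
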