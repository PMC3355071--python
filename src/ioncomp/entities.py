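"""Typed entities and name-indexed environments.

A declaration in the equation-oriented language becomes exactly one entity:

====================  ==============  ===============================
declaration           entity kind     meaning
====================  ==============  ===============================
``(const x = e)``     PARAMETER       constant during integration
``(x = e)``           ASSIGNMENT      algebraic equation
``(fun f (a) = e)``   RELATION        function of its formals
``(d (x) = e)``       RATE            ODE  dx/dt = e
``(reaction ...)``    REACTION        mass-action kinetic scheme
====================  ==============  ===============================

Entities live in :class:`Environment` structures, which may nest (one per
model component) and are later flattened to a single namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

from .errors import GrammarError, RedefinitionError, ValidationError
from .expr import Expr, Neg, Num, free_vars, parse_expr_items
from .sexpr import Op, SList, Sym, SyntaxNode

__all__ = [
    "PARAMETER", "ASSIGNMENT", "RELATION", "RATE", "REACTION",
    "Entity", "Transition", "Environment", "build_entity", "extend_env",
]

PARAMETER = "PARAMETER"
ASSIGNMENT = "ASSIGNMENT"
RELATION = "RELATION"
RATE = "RATE"
REACTION = "REACTION"

_DECL_HEADS = {"const", "fun", "d", "reaction"}


@dataclass(frozen=True)
class Transition:
    src: str
    dst: str
    fwd: Expr
    rev: Optional[Expr] = None  # absent for forward-only transitions


@dataclass(frozen=True)
class Entity:
    name: str
    kind: str
    rhs: Optional[Expr] = None                  # PARAMETER/ASSIGNMENT/RELATION/RATE
    formals: Tuple[str, ...] = ()               # RELATION
    state: Optional[str] = None                 # RATE
    states: Tuple[str, ...] = ()                # REACTION
    transitions: Tuple[Transition, ...] = ()    # REACTION
    conserve: float = 1.0                       # REACTION
    open_state: Optional[str] = None            # REACTION
    open_power: int = 1                         # REACTION
    # how the reference integrator initializes a RATE's state:
    #   ("voltage",) | ("gate_ab", alpha, beta) | ("gate_inftau", inf, tau)
    #   | ("reaction", scheme_name) | ("expr", e) | ("zero",)
    init: Tuple = ("zero",)

    def with_(self, **kw) -> "Entity":
        return replace(self, **kw)


class Environment:
    """Ordered name -> (Entity | Environment) map with component metadata."""

    def __init__(self, ctype: Optional[str] = None, cname: Optional[str] = None,
                 outputs: Optional[List[str]] = None):
        self.entries: Dict[str, Union[Entity, "Environment"]] = {}
        self.ctype = ctype
        self.cname = cname
        self.outputs: List[str] = list(outputs or [])
        self.meta: Dict = {}

    def bind(self, name: str, value) -> None:
        if name in self.entries:
            raise RedefinitionError(f"name {name!r} already bound in this environment")
        self.entries[name] = value

    def extend(self, name: str, value) -> "Environment":
        """Persistent extension: a new environment, the old one unchanged."""
        if name in self.entries:
            raise RedefinitionError(f"name {name!r} already bound in this environment")
        new = Environment(self.ctype, self.cname, self.outputs)
        new.entries = dict(self.entries)
        new.entries[name] = value
        new.meta = dict(self.meta)
        return new

    def lookup(self, name: str):
        return self.entries.get(name)

    def entities(self):
        return ((n, e) for n, e in self.entries.items() if isinstance(e, Entity))

    def children(self):
        return ((n, e) for n, e in self.entries.items() if isinstance(e, Environment))

    def __contains__(self, name):
        return name in self.entries

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def __repr__(self):
        kind = self.ctype or "env"
        return f"<Environment {kind} {self.cname or ''} [{', '.join(self.entries)}]>"


def extend_env(env: Environment, entity_or_child) -> Environment:
    """Extend *env* with an entity or child environment (persistent)."""
    if isinstance(entity_or_child, Entity):
        name = entity_or_child.name
    else:
        name = entity_or_child.cname or entity_or_child.ctype
        if name is None:
            raise GrammarError("child environment has neither name nor type")
    return env.extend(name, entity_or_child)


# ---------------------------------------------------------------------------
# Declaration forms -> entities
# ---------------------------------------------------------------------------

def _expect_sym(item: SyntaxNode, what: str) -> str:
    if not isinstance(item, Sym):
        raise GrammarError(f"expected {what}, got {item!r}")
    return item.name


def _expect_eq(item: SyntaxNode, context: str) -> None:
    if not (isinstance(item, Op) and item.name == "="):
        raise GrammarError(f"expected '=' in {context}, got {item!r}")


def _build_const(node: SList) -> Entity:
    if len(node) < 4:
        raise GrammarError(f"malformed const declaration: {node!r}")
    name = _expect_sym(node[1], "constant name")
    _expect_eq(node[2], "const declaration")
    rhs = parse_expr_items(node.items[3:])
    fv = free_vars(rhs)
    if fv:
        raise GrammarError(
            f"constant {name!r} must not reference free symbols: {sorted(fv)}")
    return Entity(name=name, kind=PARAMETER, rhs=rhs)


def _build_relation(node: SList) -> Entity:
    if len(node) < 5 or not isinstance(node[2], SList):
        raise GrammarError(f"malformed relation declaration: {node!r}")
    name = _expect_sym(node[1], "relation name")
    formals = tuple("v" if f == "V" else f
                    for f in (_expect_sym(x, "relation formal") for x in node[2]))
    _expect_eq(node[3], "relation declaration")
    rhs = parse_expr_items(node.items[4:])
    return Entity(name=name, kind=RELATION, formals=formals, rhs=rhs)


def _build_rate(node: SList) -> Entity:
    if len(node) < 4 or not isinstance(node[1], SList) or len(node[1]) != 1:
        raise GrammarError(f"malformed rate declaration: {node!r}")
    state = _expect_sym(node[1][0], "state name")
    _expect_eq(node[2], "rate declaration")
    rhs = parse_expr_items(node.items[3:])
    return Entity(name=state, kind=RATE, state=state, rhs=rhs)


_ARROWS = {"->": False, "<-": True, "<->": True}


def _build_transition(node: SyntaxNode) -> Transition:
    if not isinstance(node, SList) or len(node) < 4:
        raise GrammarError(f"malformed transition: {node!r}")
    arrow = _expect_sym(node[0], "transition arrow")
    if arrow not in _ARROWS:
        raise GrammarError(f"unknown transition arrow {arrow!r}")
    reversible = _ARROWS[arrow]
    src = _expect_sym(node[1], "source state")
    dst = _expect_sym(node[2], "destination state")
    if reversible:
        if len(node) != 5:
            raise GrammarError(
                f"reversible transition needs forward and reverse rates: {node!r}")
        fwd = parse_expr_items([node[3]])
        rev = parse_expr_items([node[4]])
        return Transition(src, dst, fwd, rev)
    if len(node) != 4:
        raise GrammarError(f"forward transition takes one rate: {node!r}")
    return Transition(src, dst, parse_expr_items([node[3]]), None)


def _connected(states, transitions) -> bool:
    if not states:
        return False
    adj = {s: set() for s in states}
    for tr in transitions:
        adj[tr.src].add(tr.dst)
        adj[tr.dst].add(tr.src)
    seen = {states[0]}
    stack = [states[0]]
    while stack:
        for nxt in adj[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return len(seen) == len(states)


def _build_reaction(node: SList) -> Entity:
    name = _expect_sym(node[1], "reaction name")
    declared_states: Optional[Tuple[str, ...]] = None
    transitions: List[Transition] = []
    conserve = 1.0
    open_state = None
    open_power = 1
    for clause in node.items[2:]:
        if not isinstance(clause, SList) or clause.head is None:
            raise GrammarError(f"malformed reaction clause: {clause!r}")
        head = clause.head
        if head == "states":
            declared_states = tuple(_expect_sym(s, "state name") for s in clause[1:])
        elif head == "transitions":
            transitions.extend(_build_transition(t) for t in clause[1:])
        elif head == "conserve":
            e = parse_expr_items(clause.items[1:])
            if isinstance(e, Num):
                conserve = e.value
            elif isinstance(e, Neg) and isinstance(e.arg, Num):
                conserve = -e.arg.value
            else:
                raise GrammarError("conserve clause must be a numeric literal")
        elif head == "open":
            open_state = _expect_sym(clause[1], "open state")
            for sub in clause[2:]:
                if isinstance(sub, SList) and sub.head == "power":
                    open_power = int(sub[1].value)
                else:
                    raise GrammarError(f"malformed open clause: {clause!r}")
        else:
            raise GrammarError(f"unknown reaction clause {head!r}")
    if not transitions:
        raise GrammarError(f"reaction {name!r} declares no transitions")
    seen: List[str] = []
    for tr in transitions:
        for s in (tr.src, tr.dst):
            if s not in seen:
                seen.append(s)
    states = declared_states if declared_states is not None else tuple(seen)
    undeclared = [s for s in seen if s not in states]
    if undeclared:
        raise GrammarError(
            f"reaction {name!r}: transition references undeclared state(s) {undeclared}")
    if not _connected(list(states), transitions):
        raise GrammarError(f"reaction {name!r}: transition graph is not connected")
    if open_state is not None and open_state not in states:
        raise GrammarError(f"reaction {name!r}: open state {open_state!r} not a member")
    if open_power < 1:
        raise ValidationError(f"reaction {name!r}: open-state power must be >= 1")
    return Entity(name=name, kind=REACTION, states=states,
                  transitions=tuple(transitions), conserve=conserve,
                  open_state=open_state, open_power=open_power)


def build_entity(decl: SyntaxNode) -> Entity:
    """Map one declaration form to its entity."""
    if not isinstance(decl, SList) or not decl.items:
        raise GrammarError(f"not a declaration: {decl!r}")
    head = decl.head
    if head == "const":
        return _build_const(decl)
    if head == "fun":
        return _build_relation(decl)
    if head == "d":
        return _build_rate(decl)
    if head == "reaction":
        return _build_reaction(decl)
    # algebraic equation:  (x = e)
    if (head is not None and len(decl) >= 3
            and isinstance(decl[1], Op) and decl[1].name == "="):
        name = decl[0].name
        rhs = parse_expr_items(decl.items[2:])
        return Entity(name=name, kind=ASSIGNMENT, rhs=rhs)
    raise GrammarError(f"unknown declaration head {head!r}")
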