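"""Dependency ordering and the solver-ready system representation.

The target structure is a 5-tuple: an ordered list of parameters and
algebraic assignments (each entry after everything it references), a list of
relations (kept as callable definitions, not inlined), the list of
differential equations, and a dense state-name -> index map; kinetic schemes
additionally travel as expanded reaction records so that code generators can
emit them natively (NMODL KINETIC blocks, steady-state initialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .entities import (ASSIGNMENT, PARAMETER, RATE, REACTION, RELATION,
                       Entity, Environment)
from .errors import CycleError, EmptySystemError, RedefinitionError, \
    UnresolvedReferenceError
from .expr import Expr, free_vars
from .lower import RESERVED_GLOBALS, CurrentIR, PoolIR

__all__ = ["OdeSystem", "ModelInfo", "CurrentRecord", "order_entities",
           "build_ode_system", "build_model_info"]


@dataclass
class OdeSystem:
    """Ordered, flat system of equations ready for code generation."""
    name: str
    defs: List[Tuple[str, str, Expr]]          # (name, PARAMETER|ASSIGNMENT, rhs)
    relations: List[Entity]
    odes: List[Tuple[str, Expr]]               # (state, d state/dt)
    state_index: Dict[str, int]
    reactions: List[Entity] = field(default_factory=list)
    init: Dict[str, Tuple] = field(default_factory=dict)
    currents: List[CurrentIR] = field(default_factory=list)
    pools: List[PoolIR] = field(default_factory=list)
    capacitance: Optional[str] = None

    @property
    def n_states(self) -> int:
        return len(self.state_index)

    @property
    def states(self) -> List[str]:
        return [s for s, _ in self.odes]

    def relations_map(self) -> Dict[str, Entity]:
        return {r.name: r for r in self.relations}

    def reaction_states(self) -> frozenset:
        return frozenset(s for r in self.reactions for s in r.states)


def _stable_toposort(names: List[str], deps: Dict[str, set]) -> List[str]:
    """Kahn's algorithm keeping source order among ready entries."""
    order = {n: i for i, n in enumerate(names)}
    indeg = {n: 0 for n in names}
    users: Dict[str, List[str]] = {n: [] for n in names}
    for n in names:
        for d in deps[n]:
            indeg[n] += 1
            users[d].append(n)
    ready = sorted([n for n in names if indeg[n] == 0], key=order.__getitem__)
    out = []
    while ready:
        n = ready.pop(0)
        out.append(n)
        changed = False
        for u in users[n]:
            indeg[u] -= 1
            if indeg[u] == 0:
                ready.append(u)
                changed = True
        if changed:
            ready.sort(key=order.__getitem__)
    if len(out) != len(names):
        remaining = [n for n in names if n not in set(out)]
        # walk dependency links among the stragglers to surface one cycle
        start = remaining[0]
        seen, cur = [], start
        while cur not in seen:
            seen.append(cur)
            cur = next(iter(d for d in deps[cur] if d in remaining))
        cycle = seen[seen.index(cur):] + [cur]
        raise CycleError(cycle)
    return out


def order_entities(flat: Environment) -> Environment:
    """Order parameters/assignments/relations by their dependencies.

    States and reserved globals are roots of the partial order.  Validates
    that every referenced identifier resolves to an entry, a state, a reserved
    global or a relation formal.
    """
    defs, relations, rates, reactions = [], [], [], []
    for name, ent in flat.entities():
        if ent.kind in (PARAMETER, ASSIGNMENT):
            defs.append(ent)
        elif ent.kind == RELATION:
            relations.append(ent)
        elif ent.kind == RATE:
            rates.append(ent)
        elif ent.kind == REACTION:
            reactions.append(ent)

    states = {r.name for r in rates}
    orderable = {e.name for e in defs} | {e.name for e in relations}
    known = orderable | states | RESERVED_GLOBALS

    def check(ent: Entity, refs):
        shadow = set(ent.formals)
        for ref in refs:
            if ref not in known and ref not in shadow:
                raise UnresolvedReferenceError(
                    f"identifier {ref!r} referenced by {ent.name!r} is "
                    f"undefined in the flattened model")

    deps: Dict[str, set] = {}
    for ent in defs + relations:
        refs = free_vars(ent.rhs) - set(ent.formals)
        check(ent, refs)
        deps[ent.name] = {r for r in refs if r in orderable}
    for ent in rates:
        check(ent, free_vars(ent.rhs))
        if ent.init and len(ent.init) > 1 and ent.init[0] != "reaction":
            for e in ent.init[1:]:
                check(ent, free_vars(e))
    for ent in reactions:
        for t in ent.transitions:
            check(ent, free_vars(t.fwd))
            if t.rev is not None:
                check(ent, free_vars(t.rev))

    by_name = {e.name: e for e in defs + relations}
    ordered_names = _stable_toposort([e.name for e in defs + relations], deps)

    ordered = Environment(ctype=flat.ctype, cname=flat.cname)
    ordered.meta = dict(flat.meta)
    for n in ordered_names:
        ordered.bind(n, by_name[n])
    for ent in reactions:
        ordered.bind(ent.name, ent)
    for ent in rates:
        ordered.bind(ent.name, ent)
    return ordered


def build_ode_system(ordered: Environment) -> OdeSystem:
    """Assemble the 5-tuple from an ordered environment."""
    defs, relations, odes, reactions = [], [], [], []
    init: Dict[str, Tuple] = {}
    for name, ent in ordered.entities():
        if ent.kind in (PARAMETER, ASSIGNMENT):
            defs.append((name, ent.kind, ent.rhs))
        elif ent.kind == RELATION:
            relations.append(ent)
        elif ent.kind == REACTION:
            reactions.append(ent)
        elif ent.kind == RATE:
            odes.append((name, ent.rhs))
            init[name] = ent.init
    if not odes:
        raise EmptySystemError("model contains no differential equations")
    state_index = {s: i for i, (s, _) in enumerate(odes)}
    meta = ordered.meta
    return OdeSystem(name=meta.get("model_name", "model"),
                     defs=defs, relations=relations, odes=odes,
                     state_index=state_index, reactions=reactions, init=init,
                     currents=list(meta.get("currents", [])),
                     pools=list(meta.get("pools", [])),
                     capacitance=meta.get("capacitance"))


@dataclass(frozen=True)
class CurrentRecord:
    """NMODL-facing description of one ionic current."""
    name: str                       # component name (mechanism suffix)
    ion: str                        # species token or "non-specific"
    ion_current: Optional[str]      # e.g. "ina"; None for non-specific
    reversal: Optional[str]         # e.g. "ena"; None for non-specific / GHK
    accumulating: Optional[str]     # ion whose pool consumes this current
    range_vars: Tuple[str, ...]


@dataclass
class ModelInfo:
    name: str
    records: List[CurrentRecord]

    def by_species(self) -> Dict[str, List[CurrentRecord]]:
        out: Dict[str, List[CurrentRecord]] = {}
        for r in self.records:
            out.setdefault(r.ion, []).append(r)
        return out


def build_model_info(sys: OdeSystem) -> ModelInfo:
    """Ion metadata per current: names are built by concatenating the species
    token (current ``i<ion>``, reversal ``e<ion>``), the convention NMODL's
    USEION statements require."""
    records = []
    seen = set()
    for cur in sys.currents:
        nonspecific = cur.species == "non-specific"
        ion_current = None if nonspecific else "i" + cur.species
        reversal = None if (nonspecific or cur.law == "ghk") else "e" + cur.species
        range_vars = tuple(v for v in (cur.gbar_name, cur.g_name, cur.i_name) if v)
        if cur.name in seen:
            raise RedefinitionError(f"two currents generate the name {cur.name!r}")
        seen.add(cur.name)
        records.append(CurrentRecord(name=cur.name, ion=cur.species,
                                     ion_current=ion_current, reversal=reversal,
                                     accumulating=cur.accumulating,
                                     range_vars=range_vars))
    return ModelInfo(name=sys.name, records=records)
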