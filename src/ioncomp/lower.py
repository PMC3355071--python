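"""Semantic lowering: component tree -> flat environment of equations.

The pipeline implemented here:

1. ``build_component_env`` mirrors the component tree as nested environments,
   expanding gates, templates and kinetic schemes *inside* their own scope;
2. ``flatten`` rewrites the nested environments into a single namespace,
   prefixing every entity name with its component path and substituting all
   references accordingly;
3. current, pool and membrane-potential equations are assembled over the
   flattened names;
4. ``resolve_inputs`` turns every ``input (x from type name)`` declaration
   into an algebraic assignment bound to the source component's output.

Reserved globals (``v``, ``t``, ``celsius``, ``stim`` and the input-wired
names) cross component boundaries unmangled.
"""

from __future__ import annotations

import re
from collections import ChainMap
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import ghk as _ghk  # noqa: F401  (registers the ghk builtin)
from .components import (DECAYING_POOL, GATING, HH_GATING, MEMBRANE_CAPACITANCE,
                         NON_SPECIFIC, OHMIC_CURRENT, PERMEABILITY,
                         PERMEATING_ION, PORE, ComponentDecl, Model)
from .currents import (assemble_ghk_current, assemble_membrane_potential,
                       assemble_ohmic_current, expand_decaying_pool,
                       expand_hh_gating, expand_reaction)
from .entities import (ASSIGNMENT, PARAMETER, RATE, REACTION, RELATION,
                       Entity, Environment, Transition, build_entity)
from .errors import (AmbiguityError, NamingError, OutputContractError,
                     RedefinitionError, StructuralError,
                     UnresolvedReferenceError, WiringError)
from .expr import Binary, Num, Sym, free_vars, subst

__all__ = ["RESERVED_GLOBALS", "CurrentIR", "PoolIR", "build_component_env",
           "flatten", "resolve_inputs", "lower_model"]

RESERVED_GLOBALS = {"v", "t", "celsius", "stim"}

_IDENT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


def sanitize(name: str) -> str:
    out = name.replace("-", "_").replace("'", "_")
    if not _IDENT_RE.match(out):
        raise NamingError(f"cannot mangle {name!r} into a legal identifier")
    return out


def flat_name(path: Tuple[str, ...], name: str) -> str:
    return "_".join([*path, sanitize(name)])


@dataclass
class CurrentIR:
    """Per-current record used by code generation (USEION/RANGE etc.)."""
    name: str                      # component name, e.g. Na
    law: str                       # "ohmic" | "ghk"
    species: str                   # lowercase ion token or "non-specific"
    i_name: str                    # flattened current entity
    g_name: Optional[str]          # flattened conductance entity (ohmic)
    gbar_name: Optional[str]       # flattened gbar / pmax parameter
    e_name: Optional[str] = None   # flattened reversal (ohmic)
    valence: Optional[int] = None  # ghk
    gates: List[Tuple[str, int]] = field(default_factory=list)
    reactions: List[str] = field(default_factory=list)
    accumulating: Optional[str] = None  # ion accumulated by a pool


@dataclass
class PoolIR:
    name: str
    ion: str
    out_name: str                  # flattened concentration state
    source_currents: List[str]     # component names of consumed currents
    i_names: List[str] = field(default_factory=list)
    src_name: str = ""             # flattened total-source-current assignment


_POOL_SOURCE = "isrc"  # synthesized per-pool total-source-current assignment


# ---------------------------------------------------------------------------
# Stage 1: component tree -> nested environments
# ---------------------------------------------------------------------------

def build_component_env(comp: ComponentDecl) -> Environment:
    """Nested environment mirroring *comp*; gates/templates/schemes expanded.

    Raises an output-contract error when a declared output is not defined,
    and a redefinition error for duplicate sibling names.
    """
    env = Environment(ctype=comp.ctype, cname=comp.cname, outputs=list(comp.outputs))

    for decl in comp.entity_decls:
        ent = build_entity(decl)
        env.bind(ent.name, ent)

    # kinetic schemes expand to one RATE per state, in this same scope
    for ent in [e for _, e in env.entities() if e.kind == REACTION]:
        for state_ent in expand_reaction(ent):
            env.bind(state_ent.name, state_ent)

    gates: List[Tuple[str, int]] = []
    if comp.gates:  # compact (gating m (power 3) ...) form
        for g in comp.gates:
            env.bind(g.name, expand_hh_gating(g))
            gates.append((g.name, g.power))
        if not env.outputs:
            env.outputs = [g.name for g in comp.gates]
    elif comp.ctype == HH_GATING:
        # template: equations must be named exactly <g>_inf and tau_<g>
        for g in comp.outputs:
            for required in (f"{g}_inf", f"tau_{g}"):
                if required not in env:
                    raise StructuralError(
                        f"HH-gating-dynamics template for gate {g!r} must "
                        f"contain an equation called {required!r}")
            m = Sym(g)
            rhs = Binary("/", Binary("-", Sym(f"{g}_inf"), m), Sym(f"tau_{g}"))
            env.bind(g, Entity(name=g, kind=RATE, state=g, rhs=rhs,
                               init=("gate_inftau", Sym(f"{g}_inf"), Sym(f"tau_{g}"))))
            gates.append((g, comp.powers.get(g, 1)))
    elif comp.ctype == GATING:
        # structured form: outputs name the gate states defined in the body
        reactions = [e for _, e in env.entities() if e.kind == REACTION]
        for g in comp.outputs:
            owner = next((r for r in reactions if r.open_state == g), None)
            if owner is not None:
                gates.append((g, owner.open_power))
            elif g in env and env.lookup(g).kind == RATE:
                gates.append((g, comp.powers.get(g, 1)))
            else:
                raise OutputContractError(
                    f"gating output {g!r} is not defined by a rate equation "
                    f"or kinetic scheme")
    env.meta["gates"] = gates

    if comp.ctype == DECAYING_POOL:
        _lower_pool_scope(comp, env)

    used_keys = set()
    for child in comp.children:
        child_env = build_component_env(child)
        key = child.cname
        if key is None:
            key = child.ctype
            n = 2
            while key in used_keys:
                key = f"{child.ctype}-{n}"
                n += 1
        used_keys.add(key)
        env.bind(key, child_env)  # duplicate *named* siblings -> redefinition

    for out in env.outputs:
        if out not in env or isinstance(env.lookup(out), Environment):
            raise OutputContractError(
                f"component {comp.cname or comp.ctype}: declared output "
                f"{out!r} is not defined in its body")
    return env


def _lower_pool_scope(comp: ComponentDecl, env: Environment) -> None:
    label = comp.cname or DECAYING_POOL
    if len(comp.outputs) != 1:
        raise StructuralError(
            f"decaying-pool {label}: exactly one exported concentration "
            f"expected, got {comp.outputs}")
    for required in ("B", "steady", "tau"):
        if required not in env:
            raise StructuralError(
                f"decaying-pool {label}: must define a constant named "
                f"{required!r}")
    out = comp.outputs[0]
    # the total source current is patched in after currents are assembled
    env.bind(_POOL_SOURCE, Entity(name=_POOL_SOURCE, kind=ASSIGNMENT, rhs=Num(0.0)))
    env.bind(out, expand_decaying_pool(out, "B", "steady", "tau", [_POOL_SOURCE]))


# ---------------------------------------------------------------------------
# Stage 2: flattening
# ---------------------------------------------------------------------------

def _rewrite_entity(ent: Entity, new_name: str, chain: ChainMap) -> Entity:
    if ent.kind == RELATION:
        shadow = frozenset(ent.formals)
        return ent.with_(name=new_name, rhs=subst(ent.rhs, chain, shadow))
    if ent.kind == REACTION:
        def rename(s):
            mapped = chain.get(s)
            return mapped.name if isinstance(mapped, Sym) else s
        transitions = tuple(
            Transition(rename(t.src), rename(t.dst), subst(t.fwd, chain),
                       None if t.rev is None else subst(t.rev, chain))
            for t in ent.transitions)
        return ent.with_(name=new_name,
                         states=tuple(rename(s) for s in ent.states),
                         transitions=transitions,
                         open_state=rename(ent.open_state) if ent.open_state else None)
    init = ent.init
    if init and len(init) > 1:
        if init[0] == "reaction":
            mapped = chain.get(init[1])
            init = ("reaction", mapped.name if isinstance(mapped, Sym) else init[1])
        else:
            init = (init[0],) + tuple(subst(e, chain) for e in init[1:])
    new = ent.with_(name=new_name, init=init)
    if ent.rhs is not None:
        new = new.with_(rhs=subst(ent.rhs, chain))
    if ent.kind == RATE:
        new = new.with_(state=new_name)
    return new


def flatten(root_env: Environment, wired: frozenset = frozenset()) -> Environment:
    """Rewrite nested environments into one namespace with path-prefixed names."""
    flat = Environment(ctype=root_env.ctype, cname=root_env.cname)
    flat.meta["gate_map"] = {}  # (path, local state) -> flat state
    passthrough = RESERVED_GLOBALS | wired

    def walk(env: Environment, path: Tuple[str, ...], parent_chain: ChainMap):
        local = {name: Sym(flat_name(path, name)) for name, _ in env.entities()}
        chain = parent_chain.new_child(local)
        for name, ent in env.entities():
            fname = flat_name(path, name)
            shadow = frozenset(ent.formals) if ent.kind == RELATION else frozenset()
            refs = set()
            if ent.rhs is not None:
                refs |= free_vars(ent.rhs)
            for t in ent.transitions:
                refs |= free_vars(t.fwd)
                if t.rev is not None:
                    refs |= free_vars(t.rev)
            if ent.init and len(ent.init) > 1 and ent.init[0] != "reaction":
                for e in ent.init[1:]:
                    refs |= free_vars(e)
            for ref in refs:
                if ref in shadow or ref in chain or ref in passthrough:
                    continue
                raise UnresolvedReferenceError(
                    f"identifier {ref!r} referenced by {name!r} (component "
                    f"{'/'.join(path) or '<root>'}) is not defined in any "
                    f"enclosing scope")
            if fname in flat:
                raise RedefinitionError(f"flattening collision on {fname!r}")
            flat.bind(fname, _rewrite_entity(ent, fname, chain))
            if ent.kind == RATE:
                flat.meta["gate_map"][(path, name)] = fname
        for key, child in env.children():
            walk(child, path + (sanitize(key),), chain)

    walk(root_env, (), ChainMap({}))
    return flat


# ---------------------------------------------------------------------------
# Stage 3/4: wiring and current assembly
# ---------------------------------------------------------------------------

def _decl_paths(root: ComponentDecl) -> Dict[int, Tuple[str, ...]]:
    """Component path of every declaration, using the stage-1 key policy."""
    paths: Dict[int, Tuple[str, ...]] = {id(root): ()}

    def walk(comp: ComponentDecl, path):
        used = set()
        for child in comp.children:
            key = child.cname
            if key is None:
                key = child.ctype
                n = 2
                while key in used:
                    key = f"{child.ctype}-{n}"
                    n += 1
            used.add(key)
            cpath = path + (sanitize(key),)
            paths[id(child)] = cpath
            walk(child, cpath)

    walk(root, ())
    return paths


def collect_inputs(root: ComponentDecl):
    return [d for comp in root.walk() for d in comp.inputs]


def resolve_inputs(flat: Environment, model: Model,
                   paths: Optional[Dict[int, Tuple[str, ...]]] = None) -> None:
    """Bind every input-wired local name to its source component's output."""
    root = model.root
    if paths is None:
        paths = _decl_paths(root)
    for decl in collect_inputs(root):
        sources = [c for c in root.walk()
                   if c.ctype == decl.source_ctype and c.cname == decl.source_cname]
        if not sources:
            raise WiringError(
                f"input {decl.local!r}: no component of type "
                f"{decl.source_ctype!r} named {decl.source_cname!r}")
        src = sources[0]
        if decl.source_output is not None:
            if decl.source_output not in src.outputs:
                raise WiringError(
                    f"input {decl.local!r}: component {decl.source_cname!r} "
                    f"does not export {decl.source_output!r}")
            out = decl.source_output
        elif len(src.outputs) == 1:
            out = src.outputs[0]
        else:
            raise AmbiguityError(
                f"input {decl.local!r}: component {decl.source_cname!r} "
                f"exports {len(src.outputs)} outputs; name one explicitly")
        target = flat_name(paths[id(src)], out)
        if target not in flat:
            raise WiringError(
                f"input {decl.local!r}: source output {target!r} missing "
                f"from the flattened model")
        flat.bind(decl.local, Entity(name=decl.local, kind=ASSIGNMENT,
                                     rhs=Sym(target)))


def _sole_output(comp: ComponentDecl, env_names, fallback: str, what: str) -> str:
    if comp.outputs:
        return comp.outputs[0]
    if fallback in env_names:
        return fallback
    raise StructuralError(f"{what}: no declared output and no {fallback!r} entity")


def _gating_children(cur: ComponentDecl):
    return [c for c in cur.children if c.ctype in (GATING, HH_GATING)]


def _nested_lookup(nested: Environment, path: Tuple[str, ...]):
    env = nested
    for seg in path:
        env = next(child for key, child in env.children()
                   if sanitize(key) == seg)
    return env


def _concentration(ion_comp: ComponentDecl, ion_env: Environment, ion: str,
                   side: str, path, wired: frozenset):
    """Expression for an internal ('i') or external ('o') concentration."""
    for candidate in (f"c{side}", f"{ion}{side}"):
        if candidate in ion_env:
            return Sym(flat_name(path, candidate))
    if f"{ion}{side}" in wired:
        return Sym(f"{ion}{side}")
    raise UnresolvedReferenceError(
        f"GHK current: {'internal' if side == 'i' else 'external'} "
        f"concentration of {ion!r} is neither defined nor input-wired")


def lower_model(model: Model) -> Environment:
    """Full lowering of a validated model to a flat, unordered environment."""
    root = model.root
    paths = _decl_paths(root)
    wired = frozenset(d.local for d in collect_inputs(root))

    nested = build_component_env(root)
    nested_children = dict(nested.children())
    flat = flatten(nested, wired)

    # reserved globals that are plain parameters unless the model defines them
    if "celsius" not in flat:
        flat.bind("celsius", Entity(name="celsius", kind=PARAMETER, rhs=Num(22.0)))
    flat.bind("stim", Entity(name="stim", kind=PARAMETER, rhs=Num(0.0)))

    currents: List[CurrentIR] = []
    for cur in root.children_of_type(OHMIC_CURRENT):
        path = paths[id(cur)]
        label = cur.cname or "current"
        gates: List[Tuple[str, int]] = []
        reaction_names: List[str] = []
        for gc in _gating_children(cur):
            gpath = paths[id(gc)]
            genv = _nested_lookup(nested, gpath)
            for state, power in genv.meta.get("gates", []):
                gates.append((flat_name(gpath, state), power))
            reaction_names.extend(flat_name(gpath, n) for n, e in genv.entities()
                                  if e.kind == REACTION)
        ion_comp = cur.children_of_type(PERMEATING_ION)[0]
        ion_env = _nested_lookup(nested, paths[id(ion_comp)])
        species = (ion_comp.cname or NON_SPECIFIC).lower()
        g_name = flat_name(path, "g")
        i_name = flat_name(path, "i")

        pores = cur.children_of_type(PORE)
        if pores:
            pore_env = _nested_lookup(nested, paths[id(pores[0])])
            gbar = flat_name(paths[id(pores[0])],
                             _sole_output(pores[0], pore_env.entries, "gbar",
                                          f"current {label} pore"))
            e_name = flat_name(paths[id(ion_comp)],
                               _sole_output(ion_comp, ion_env.entries, "e",
                                            f"current {label} permeating-ion"))
            for ent in assemble_ohmic_current(g_name, i_name, gbar, e_name, gates):
                flat.bind(ent.name, ent)
            currents.append(CurrentIR(name=label, law="ohmic", species=species,
                                      i_name=i_name, g_name=g_name,
                                      gbar_name=gbar, e_name=e_name,
                                      gates=gates, reactions=reaction_names))
        else:
            perm = cur.children_of_type(PERMEABILITY)[0]
            perm_env = _nested_lookup(nested, paths[id(perm)])
            pmax = flat_name(paths[id(perm)],
                             _sole_output(perm, perm_env.entries, "pmax",
                                          f"current {label} permeability"))
            ci = _concentration(ion_comp, ion_env, species, "i",
                                paths[id(ion_comp)], wired)
            co = _concentration(ion_comp, ion_env, species, "o",
                                paths[id(ion_comp)], wired)
            for ent in assemble_ghk_current(i_name, pmax, gates, ci, co,
                                            ion_comp.valence):
                flat.bind(ent.name, ent)
            currents.append(CurrentIR(name=label, law="ghk", species=species,
                                      i_name=i_name, g_name=None,
                                      gbar_name=pmax, valence=ion_comp.valence,
                                      gates=gates, reactions=reaction_names))

    by_name = {c.name: c for c in currents}
    pools: List[PoolIR] = []
    for pool in root.children_of_type(DECAYING_POOL):
        path = paths[id(pool)]
        label = pool.cname or DECAYING_POOL
        missing = [n for n in pool.source_currents if n not in by_name]
        if missing:
            raise WiringError(
                f"decaying-pool {label}: source current(s) {missing} not found")
        i_names = [by_name[n].i_name for n in pool.source_currents]
        src_name = flat_name(path, _POOL_SOURCE)
        total = Sym(i_names[0])
        for n in i_names[1:]:
            total = Binary("+", total, Sym(n))
        flat.entries[src_name] = Entity(name=src_name, kind=ASSIGNMENT, rhs=total)
        ion = (pool.cname or "ca").lower()
        pools.append(PoolIR(name=label, ion=ion,
                            out_name=flat_name(path, pool.outputs[0]),
                            source_currents=list(pool.source_currents),
                            i_names=i_names, src_name=src_name))
        for cname in pool.source_currents:
            by_name[cname].accumulating = ion

    cap = root.children_of_type(MEMBRANE_CAPACITANCE)[0]
    cap_env = _nested_lookup(nested, paths[id(cap)])
    c_name = flat_name(paths[id(cap)],
                       _sole_output(cap, cap_env.entries, "C",
                                    "membrane-capacitance"))
    vrate = assemble_membrane_potential([c.i_name for c in currents], c_name)
    flat.bind("v", vrate)

    resolve_inputs(flat, model, paths)

    flat.meta["model_name"] = root.cname or "model"
    flat.meta["currents"] = currents
    flat.meta["pools"] = pools
    flat.meta["capacitance"] = c_name
    return flat
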