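"""NMODL (NEURON mechanism) code target, with automatic merging.

One ``.mod`` file per ionic current in the standard one-mechanism-per-file
layout, or a single merged mechanism whose equations are solved together.
Merging is safe because every variable already carries its component-path
prefix, so no two currents can collide on common names like ``m`` or
``gbar``; the per-species current totals (``ina``, ``ik``, ...) are formed by
summing the current equations of all channels of that species.

HH-style gates go to a DERIVATIVE block (method cnexp), kinetic schemes to
KINETIC blocks with mass-action ``~`` reactions and a CONSERVE statement
(method sparse).  In the unmerged layout a calcium pool becomes its own
mechanism (``USEION ca READ ica WRITE cai``) and GHK currents read ``cai``
back through the ion mechanism; in the merged layout the pool equations stay
internal and the mechanism writes ``cai`` itself.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Set, Tuple

from ..entities import ASSIGNMENT, PARAMETER, Entity
from ..errors import NamingError, RedefinitionError
from ..expr import Sym, eval_expr, free_vars, parse_expr, write_expr
from ..odesystem import ModelInfo, OdeSystem
from ..sexpr import format_number
from .common import def_closure, expr_to_code, uses_ghk

__all__ = ["emit_nmodl", "read_nmodl_equations"]

_IDENT = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")
_NMODL_RESERVED = {
    "v", "t", "dt", "celsius", "area", "diam", "if", "else", "while",
    "LOCAL", "TABLE", "FROM", "TO", "WITH", "SOLVE", "METHOD", "CONSERVE",
}

_UNITS_BLOCK = """\
UNITS {
    (mV) = (millivolt)
    (mA) = (milliamp)
    (mS) = (millisiemens)
    (mM) = (milli/liter)
}
"""

_GHK_FUNCTION = """\
FUNCTION ghk(v (mV), ci (mM), co (mM), z, celsius) {
    LOCAL u
    u = z * 96485.33212 * (v * 0.001) / (8.31446 * (273.15 + celsius))
    if (fabs(u) < 1e-06) {
        ghk = z * 96485.33212 * ((ci - co) + u * (ci + co) / 2.0)
    } else {
        ghk = z * 96485.33212 * u * (ci - co * exp(-u)) / (1.0 - exp(-u))
    }
}
"""


def _check_ident(name: str) -> str:
    if not _IDENT.match(name) or name in _NMODL_RESERVED - {"v", "celsius"}:
        raise NamingError(f"identifier {name!r} is not legal in NMODL")
    return name


def _code(e, rename):
    return expr_to_code(e, "nmodl", rename)


def emit_nmodl(sys: OdeSystem, info: ModelInfo, merge: bool = False
               ) -> List[Tuple[str, str]]:
    """Emit NMODL mechanism files as (filename, text) pairs."""
    cur_by_name = {c.name: c for c in sys.currents}
    if merge:
        text = _emit_mechanism(sys, info, sys.name, list(sys.currents),
                               list(sys.pools), merged=True)
        return [(f"{sys.name}.mod", text)]
    files = []
    for cur in sys.currents:
        text = _emit_mechanism(sys, info, cur.name, [cur], [], merged=False)
        files.append((f"{cur.name}.mod", text))
    for pool in sys.pools:
        text = _emit_pool_mechanism(sys, pool)
        files.append((f"{pool.name}_pool.mod", text))
    return files


def _mech_states(sys: OdeSystem, currents, pools) -> List[str]:
    wanted: Set[str] = set()
    for cur in currents:
        wanted.update(s for s, _ in cur.gates)
        for rname in cur.reactions:
            r = next(x for x in sys.reactions if x.name == rname)
            wanted.update(r.states)
    for pool in pools:
        wanted.add(pool.out_name)
    return [s for s in sys.states if s in wanted]


def _param_value(sys: OdeSystem, name: str) -> Optional[float]:
    for n, kind, e in sys.defs:
        if n == name and kind == PARAMETER:
            return eval_expr(e, {})
    return None


def _emit_mechanism(sys: OdeSystem, info: ModelInfo, suffix: str,
                    currents, pools, merged: bool) -> str:
    _check_ident(suffix)
    rec_by_name = {r.name: r for r in info.records}
    reactions = [r for r in sys.reactions
                 if any(r.name in c.reactions for c in currents)]
    if merged:
        reactions = list(sys.reactions)
    reaction_states = {s for r in reactions for s in r.states}
    states = _mech_states(sys, currents, pools)
    odes = [(s, e) for s, e in sys.odes
            if s in states and s not in reaction_states]

    # --- renaming / dropping of cross-mechanism references -----------------
    rename: Dict[str, str] = {}
    dropped: Set[str] = set()
    einit_lines: List[str] = []
    for cur in currents:
        rec = rec_by_name[cur.name]
        if rec.reversal is not None and cur.e_name:
            rename[cur.e_name] = rec.reversal
            dropped.add(cur.e_name)
            val = _param_value(sys, cur.e_name)
            if val is not None:
                line = f"{rec.reversal} = {format_number(val)}"
                if line not in einit_lines:
                    einit_lines.append(line)
    pool_states_here = {p.out_name for p in pools}
    for pool in sys.pools:
        # assignments that alias a pool concentration (input-wired names)
        for n, kind, e in sys.defs:
            if (kind == ASSIGNMENT and isinstance(e, Sym)
                    and e.name == pool.out_name
                    and pool.out_name not in pool_states_here
                    and not merged):
                rename[n] = f"{pool.ion}i"
                dropped.add(n)

    # --- dependency closure ------------------------------------------------
    roots: Set[str] = set()
    for cur in currents:
        roots.add(cur.i_name)
        if cur.g_name:
            roots.add(cur.g_name)
    for _, e in odes:
        roots |= free_vars(e)
    for r in reactions:
        for tr in r.transitions:
            roots |= free_vars(tr.fwd)
            if tr.rev is not None:
                roots |= free_vars(tr.rev)
    for s in states:
        init = sys.init.get(s, ("zero",))
        if init[0] == "reaction":
            continue
        for e in init[1:]:
            roots |= free_vars(e)
    for pool in pools:
        roots |= free_vars(dict(sys.odes)[pool.out_name])
    roots -= dropped
    defs, relations, _ = def_closure(sys, roots)
    defs = [(n, k, e) for n, k, e in defs
            if n not in dropped and n != "stim" and n not in states]
    params = [(n, e) for n, k, e in defs if k == PARAMETER]
    assigns = [(n, e) for n, k, e in defs if k == ASSIGNMENT]

    # --- NEURON block ------------------------------------------------------
    ion_use: Dict[str, Dict[str, Set[str]]] = {}
    nonspecific = False
    for cur in currents:
        rec = rec_by_name[cur.name]
        if rec.ion_current is None:
            nonspecific = True
            continue
        entry = ion_use.setdefault(rec.ion, {"read": set(), "write": set()})
        entry["write"].add(rec.ion_current)
        if rec.reversal:
            entry["read"].add(rec.reversal)
        if cur.law == "ghk":
            for target in rename.values():
                if target == f"{rec.ion}i":
                    entry["read"].add(target)
    for pool in pools:  # merged layout: pool writes the concentration
        entry = ion_use.setdefault(pool.ion, {"read": set(), "write": set()})
        entry["write"].add(f"{pool.ion}i")

    lines: List[str] = []
    w = lines.append
    w(f"NEURON {{")
    w(f"    SUFFIX {suffix}")
    for ion in sorted(ion_use):
        use = ion_use[ion]
        stmt = f"    USEION {ion}"
        if use["read"]:
            stmt += " READ " + ", ".join(sorted(use["read"]))
        if use["write"]:
            stmt += " WRITE " + ", ".join(sorted(use["write"]))
        w(stmt)
    if nonspecific:
        w("    NONSPECIFIC_CURRENT i_ns")
    range_vars = []
    for cur in currents:
        for vname in rec_by_name[cur.name].range_vars:
            if vname not in dropped and vname not in range_vars:
                range_vars.append(vname)
    if range_vars:
        w("    RANGE " + ", ".join(range_vars))
    w("}")
    w("")
    w(_UNITS_BLOCK.rstrip())
    w("")

    # --- PARAMETER / STATE / ASSIGNED --------------------------------------
    declared: List[str] = []
    w("PARAMETER {")
    for n, e in params:
        declared.append(_check_ident(n))
        w(f"    {n} = {format_number(eval_expr(e, {}))}")
    w("}")
    w("")
    if states:
        w("STATE {")
        for s in states:
            declared.append(_check_ident(s))
            w(f"    {s}")
        w("}")
        w("")
    ion_vars = {v for use in ion_use.values() for vs in use.values() for v in vs}
    ion_vars |= {f"i{ion}" for ion in ion_use}
    assigned = ["v"] + sorted(ion_vars) + (["i_ns"] if nonspecific else [])
    for n, _ in assigns:
        if n not in assigned:
            assigned.append(_check_ident(n))
    w("ASSIGNED {")
    for n in assigned:
        w(f"    {n}")
    w("}")
    w("")

    # --- INITIAL -----------------------------------------------------------
    w("INITIAL {")
    for line in einit_lines:
        w(f"    {line}")
    # resting-value states (pools) first: later assignments may read them
    for s in states:
        init = sys.init.get(s, ("zero",))
        if init[0] == "expr":
            w(f"    {s} = {_code(init[1], rename)}")
        elif init[0] == "zero":
            w(f"    {s} = 0")
    init_assigns = _needed_assigns(assigns, _init_roots(sys, states), sys)
    for n, e in init_assigns:
        if not (free_vars(e) & set(sys.state_index)) or _all_states_local(e, states):
            w(f"    {n} = {_code(e, rename)}")
    for s in states:
        init = sys.init.get(s, ("zero",))
        if init[0] == "gate_ab":
            a, b = _code(init[1], rename), _code(init[2], rename)
            w(f"    {s} = {a} / ({a} + {b})")
        elif init[0] == "gate_inftau":
            w(f"    {s} = {_code(init[1], rename)}")
    for r in reactions:
        w(f"    SOLVE kin_{r.name} STEADYSTATE sparse")
    w("}")
    w("")

    # --- BREAKPOINT --------------------------------------------------------
    w("BREAKPOINT {")
    if odes:
        w("    SOLVE states METHOD cnexp")
    for r in reactions:
        w(f"    SOLVE kin_{r.name} METHOD sparse")
    for n, e in assigns:
        w(f"    {n} = {_code(e, rename)}")
    by_ion: Dict[str, List[str]] = {}
    ns_terms: List[str] = []
    for cur in currents:
        rec = rec_by_name[cur.name]
        if rec.ion_current is None:
            ns_terms.append(cur.i_name)
        else:
            by_ion.setdefault(rec.ion_current, []).append(cur.i_name)
    for ion_cur in sorted(by_ion):
        w(f"    {ion_cur} = " + " + ".join(by_ion[ion_cur]))
    if ns_terms:
        w("    i_ns = " + " + ".join(ns_terms))
    for pool in pools:
        w(f"    {pool.ion}i = {pool.out_name}")
    w("}")
    w("")

    # --- DERIVATIVE / KINETIC ----------------------------------------------
    if odes:
        w("DERIVATIVE states {")
        for n, e in _needed_assigns(assigns, _ode_roots(odes), sys):
            w(f"    {n} = {_code(e, rename)}")
        for s, e in odes:
            w(f"    {s}' = {_code(e, rename)}")
        w("}")
        w("")
    for r in reactions:
        w(f"KINETIC kin_{r.name} {{")
        kin_roots: Set[str] = set()
        for tr in r.transitions:
            kin_roots |= free_vars(tr.fwd)
            if tr.rev is not None:
                kin_roots |= free_vars(tr.rev)
        for n, e in _needed_assigns(assigns, kin_roots, sys):
            w(f"    {n} = {_code(e, rename)}")
        for tr in r.transitions:
            fwd = _code(tr.fwd, rename)
            rev = _code(tr.rev, rename) if tr.rev is not None else "0"
            w(f"    ~ {tr.src} <-> {tr.dst} ({fwd}, {rev})")
        w(f"    CONSERVE {' + '.join(r.states)} = {format_number(r.conserve)}")
        w("}")
        w("")

    # --- FUNCTIONs ----------------------------------------------------------
    all_exprs = [e for _, e in assigns] + [e for _, e in odes]
    all_exprs += [r.rhs for r in relations]
    for r in reactions:
        for tr in r.transitions:
            all_exprs.append(tr.fwd)
            if tr.rev is not None:
                all_exprs.append(tr.rev)
    if uses_ghk(all_exprs):
        w(_GHK_FUNCTION.rstrip())
        w("")
    for rel in relations:
        declared.append(_check_ident(rel.name))
        w(f"FUNCTION {rel.name}({', '.join(rel.formals)}) {{")
        w(f"    {rel.name} = {_code(rel.rhs, rename)}")
        w("}")
        w("")

    dup = [n for n in declared if declared.count(n) > 1]
    if dup:
        raise RedefinitionError(f"duplicate identifiers in NMODL output: {dup}")
    return "\n".join(lines)


def _init_roots(sys, states) -> Set[str]:
    roots: Set[str] = set()
    for s in states:
        init = sys.init.get(s, ("zero",))
        if init[0] == "reaction":
            continue
        for e in init[1:]:
            roots |= free_vars(e)
    return roots


def _ode_roots(odes) -> Set[str]:
    roots: Set[str] = set()
    for _, e in odes:
        roots |= free_vars(e)
    return roots


def _all_states_local(e, states) -> bool:
    return all(fv in states for fv in free_vars(e) if fv in states)


def _needed_assigns(assigns, roots, sys):
    names = {n for n, _ in assigns}
    needed: Set[str] = set()
    stack = [r for r in roots if r in names]
    by_name = dict(assigns)
    while stack:
        n = stack.pop()
        if n in needed:
            continue
        needed.add(n)
        stack.extend(r for r in free_vars(by_name[n]) if r in names)
    return [(n, e) for n, e in assigns if n in needed]


def _emit_pool_mechanism(sys: OdeSystem, pool) -> str:
    """Standalone accumulation mechanism: reads ica, integrates, writes cai."""
    state = pool.out_name
    rhs = dict(sys.odes)[state]
    rename = {pool.src_name: f"i{pool.ion}"}
    roots = free_vars(rhs) - {pool.src_name}
    init = sys.init.get(state, ("zero",))
    for e in init[1:]:
        roots |= free_vars(e)
    defs, relations, _ = def_closure(sys, roots)
    params = [(n, e) for n, k, e in defs if k == PARAMETER and n != "stim"]
    assigns = [(n, e) for n, k, e in defs if k == ASSIGNMENT]

    lines: List[str] = []
    w = lines.append
    w("NEURON {")
    w(f"    SUFFIX {_check_ident(pool.name + '_pool')}")
    w(f"    USEION {pool.ion} READ i{pool.ion} WRITE {pool.ion}i")
    w(f"    RANGE {state}")
    w("}")
    w("")
    w(_UNITS_BLOCK.rstrip())
    w("")
    w("PARAMETER {")
    for n, e in params:
        w(f"    {n} = {format_number(eval_expr(e, {}))}")
    w("}")
    w("")
    w("STATE {")
    w(f"    {state}")
    w("}")
    w("")
    w("ASSIGNED {")
    w("    v")
    w(f"    i{pool.ion}")
    w(f"    {pool.ion}i")
    for n, _ in assigns:
        w(f"    {n}")
    w("}")
    w("")
    w("INITIAL {")
    if init[0] == "expr":
        w(f"    {state} = {_code(init[1], rename)}")
    else:
        w(f"    {state} = 0")
    w("}")
    w("")
    w("BREAKPOINT {")
    w("    SOLVE states METHOD cnexp")
    w(f"    {pool.ion}i = {state}")
    w("}")
    w("")
    w("DERIVATIVE states {")
    for n, e in assigns:
        w(f"    {n} = {_code(e, rename)}")
    w(f"    {state}' = {_code(rhs, rename)}")
    w("}")
    for rel in relations:
        w("")
        w(f"FUNCTION {rel.name}({', '.join(rel.formals)}) {{")
        w(f"    {rel.name} = {_code(rel.rhs, rename)}")
        w("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Minimal NMODL equation reader (for cross-checking merge correctness)
# ---------------------------------------------------------------------------

_BLOCK_RE = re.compile(r"^(NEURON|UNITS|PARAMETER|STATE|ASSIGNED|INITIAL|"
                       r"BREAKPOINT|DERIVATIVE|KINETIC|FUNCTION|PROCEDURE)\b")
_SKIP_EQ_BLOCKS = {"NEURON", "UNITS", "STATE", "ASSIGNED"}


def _split_args(text: str) -> List[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _canon(expr_text: str) -> str:
    return write_expr(parse_expr(expr_text.replace(",", " ")))


def read_nmodl_equations(text: str) -> frozenset:
    """Canonical set of the equations stated by an NMODL file.

    Collects ``lhs = rhs`` statements (parameters, assignments, derivatives,
    initial values, function bodies), ``~`` reactions and CONSERVE
    statements; each expression is re-parsed and written canonically so
    formatting differences cannot matter.  Used to verify that merged and
    per-mechanism output describe the same mathematics.
    """
    equations: Set[str] = set()
    block = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line in ("}",):
            continue
        m = _BLOCK_RE.match(line)
        if m:
            block = m.group(1)
            continue
        if block in _SKIP_EQ_BLOCKS:
            continue
        if line.startswith(("SOLVE", "LOCAL", "RANGE", "USEION", "SUFFIX")):
            continue
        if line.startswith("~"):
            m2 = re.match(r"~\s*(\w+)\s*<->\s*(\w+)\s*\((.*)\)\s*$", line)
            if m2:
                f, r = _split_args(m2.group(3))
                equations.add(f"~ {m2.group(1)} <-> {m2.group(2)} "
                              f"({_canon(f)}, {_canon(r)})")
            continue
        if line.startswith("CONSERVE"):
            lhs, rhs = line[len("CONSERVE"):].split("=", 1)
            equations.add(f"CONSERVE {_canon(lhs)} = {_canon(rhs)}")
            continue
        if line.startswith(("if", "else", "}")):
            # conditional function bodies (the GHK helper) are compared as text
            equations.add(re.sub(r"\s+", " ", line))
            continue
        if "=" in line:
            lhs, rhs = line.split("=", 1)
            lhs = lhs.strip()
            rhs = re.sub(r"\([^()]*\)\s*$", "", rhs).strip() \
                if block == "PARAMETER" else rhs.strip()
            equations.add(f"{lhs} = {_canon(rhs)}")
    return frozenset(equations)
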