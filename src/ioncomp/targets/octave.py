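"""Numeric-scripting text target (Matlab/Octave-style ``.m`` script).

The script defines the right-hand side function against the standard
solver API (state vector in, derivative vector out), one function per
relation, steady-state initialization, and a driver that integrates over
the configured duration with ``ode15s``/``lsode``-style stiff solvers.
"""

from __future__ import annotations

from typing import List, Optional

from ..odesystem import OdeSystem
from ..sexpr import format_number
from .common import def_closure, expr_to_code, split_state_dependent, uses_ghk

__all__ = ["emit_octave_script"]


def _m(e):
    return expr_to_code(e, "octave")


_GHK_M = """\
function out = ghk(v, ci, co, z, celsius)
  u = z * 96485.33212 * (v * 0.001) / (8.31446 * (273.15 + celsius));
  if (abs(u) < 1e-06)
    out = z * 96485.33212 * ((ci - co) + u * (ci + co) / 2.0);
  else
    out = z * 96485.33212 * u * (ci - co * exp(-u)) / (1.0 - exp(-u));
  end
end
"""


def _def_lines(defs, indent) -> List[str]:
    return [f"{indent}{name} = {_m(expr)};"
            for name, _kind, expr in defs if name != "stim"]


def emit_octave_script(sys: OdeSystem, cfg=None, include_driver: bool = True) -> str:
    """Emit the complete script text (deterministic)."""
    states = sys.states
    idx = sys.state_index
    duration = cfg.duration if cfg is not None else 100.0
    stepsize = cfg.stepsize if cfg is not None else 0.025
    out: List[str] = []
    w = out.append

    w(f"%% {sys.name}.m -- ODE system for model {sys.name}")
    w("%% generated code; rhs follows the standard solver API")
    w("1;")
    w("")
    w(f"function dy = {sys.name}_rhs(t, y)")
    w("  stim = 0.0;")
    for s in states:
        w(f"  {s} = y({idx[s] + 1});")
    out.extend(_def_lines(sys.defs, "  "))
    w(f"  dy = zeros({len(states)}, 1);")
    for s, e in sys.odes:
        w(f"  dy({idx[s] + 1}) = {_m(e)};")
    w("end")
    w("")
    all_exprs = [e for _, _, e in sys.defs] + [e for _, e in sys.odes]
    all_exprs += [r.rhs for r in sys.relations]
    if uses_ghk(all_exprs):
        w(_GHK_M)
        w("")
    for rel in sys.relations:
        w(f"function out = {rel.name}({', '.join(rel.formals)})")
        w(f"  out = {_m(rel.rhs)};")
        w("end")
        w("")
    _emit_initial_state(sys, w)
    if include_driver:
        w("")
        w(f"y0 = {sys.name}_init(0.0);")
        w(f"tspan = 0.0:{format_number(stepsize)}:{format_number(duration)};")
        w(f"[t, y] = ode15s(@{sys.name}_rhs, tspan, y0);")
        w("dlmwrite(stdout, [t y], '\\t');")
    return "\n".join(out) + "\n"


def _emit_initial_state(sys: OdeSystem, w) -> None:
    from ..expr import free_vars

    roots = set()
    for init in sys.init.values():
        if init[0] == "reaction":
            continue
        for e in init[1:]:
            roots |= free_vars(e)
    for r in sys.reactions:
        for tr in r.transitions:
            roots |= free_vars(tr.fwd)
            if tr.rev is not None:
                roots |= free_vars(tr.rev)
    defs, _rels, _ = def_closure(sys, roots)
    state_set = set(sys.state_index)
    pre, post = split_state_dependent(defs, state_set)
    idx = sys.state_index

    w(f"function y0 = {sys.name}_init(v0)")
    w(f"  y0 = zeros({len(state_set)}, 1);")
    w("  t = 0.0;")
    w("  stim = 0.0;")
    w("  v = v0;")
    if "v" in idx:
        w(f"  y0({idx['v'] + 1}) = v;")
    out_lines = _def_lines(pre, "  ")
    for line in out_lines:
        w(line)
    for state, init in sys.init.items():
        if init[0] == "expr":
            w(f"  {state} = {_m(init[1])};")
            w(f"  y0({idx[state] + 1}) = {state};")
        elif init[0] == "zero" and state != "v":
            w(f"  {state} = 0.0;")
    for line in _def_lines(post, "  "):
        w(line)
    for state, init in sys.init.items():
        if init[0] == "gate_ab":
            w(f"  a_ = {_m(init[1])};")
            w(f"  b_ = {_m(init[2])};")
            w(f"  {state} = a_ / (a_ + b_);")
            w(f"  y0({idx[state] + 1}) = {state};")
        elif init[0] == "gate_inftau":
            w(f"  {state} = {_m(init[1])};")
            w(f"  y0({idx[state] + 1}) = {state};")
    for r in sys.reactions:
        n = len(r.states)
        sidx = {s: i + 1 for i, s in enumerate(r.states)}
        w(f"  %% steady state of kinetic scheme {r.name}")
        w(f"  A_ = zeros({n + 1}, {n});")
        for tr in r.transitions:
            w(f"  f_ = {_m(tr.fwd)};")
            w(f"  A_({sidx[tr.dst]}, {sidx[tr.src]}) += f_;")
            w(f"  A_({sidx[tr.src]}, {sidx[tr.src]}) -= f_;")
            if tr.rev is not None:
                w(f"  r_ = {_m(tr.rev)};")
                w(f"  A_({sidx[tr.src]}, {sidx[tr.dst]}) += r_;")
                w(f"  A_({sidx[tr.dst]}, {sidx[tr.dst]}) -= r_;")
        w(f"  A_({n + 1}, :) = 1.0;")
        w(f"  b_ = zeros({n + 1}, 1);")
        w(f"  b_({n + 1}) = {format_number(r.conserve)};")
        w("  s_ = A_ \\ b_;")
        for s in r.states:
            w(f"  {s} = s_({sidx[s]});")
            w(f"  y0({idx[s] + 1}) = {s};")
    w("end")
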