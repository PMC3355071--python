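"""Solver-API code target: a Python module defining ``rhs(t, y)``.

The emitted module follows the classic ODE-solver API: ``rhs`` receives the
independent variable and the state vector and returns the derivative vector,
unpacking/packing through the state-index map.  ``initial_state(v0)``
reproduces the steady-state initialization of the reference runtime, and
``currents(t, y)`` evaluates the ionic currents for recording.

Arithmetic helpers (``_div``, ``_exp``, ...) give the emitted code the same
IEEE semantics as the in-process evaluator: division by zero and overflow
produce infinities/NaN instead of raising, so both routes agree bitwise.
"""

from __future__ import annotations

from typing import List

from ..expr import free_vars
from ..odesystem import OdeSystem
from ..sexpr import format_number
from .common import def_closure, expr_to_code, split_state_dependent, uses_ghk

__all__ = ["emit_solver_function"]

_PRELUDE = '''\
from math import exp as _raw_exp, log as _raw_log, log10, sqrt, sin, cos, tan, \\
    sinh, cosh, tanh, fabs, copysign as _copysign


def _exp(x):
    try:
        return _raw_exp(x)
    except OverflowError:
        return float("inf")


def _log(x):
    if x < 0:
        return float("nan")
    if x == 0:
        return float("-inf")
    return _raw_log(x)


def _div(a, b):
    try:
        return a / b
    except ZeroDivisionError:
        if a == 0 or a != a:
            return float("nan")
        return _copysign(float("inf"), a) * _copysign(1.0, b)


def _pow(a, b):
    try:
        return a ** b
    except (OverflowError, ValueError, ZeroDivisionError):
        return float("nan")
'''

_GHK = '''\
def ghk(v, ci, co, z, celsius):
    u = z * 96485.33212 * (v * 0.001) / (8.31446 * (273.15 + celsius))
    if fabs(u) < 1e-06:
        return z * 96485.33212 * ((ci - co) + u * (ci + co) / 2.0)
    return z * 96485.33212 * u * (ci - co * _exp(-u)) / (1.0 - _exp(-u))
'''


def _py(e, lang="python"):
    return expr_to_code(e, lang)


def _def_lines(defs, indent, skip=("stim",)) -> List[str]:
    return [f"{indent}{name} = {_py(expr)}"
            for name, _kind, expr in defs if name not in skip]


def emit_solver_function(sys: OdeSystem) -> str:
    """Emit the complete solver module text (deterministic)."""
    states = sys.states
    idx = sys.state_index
    out: List[str] = []
    w = out.append

    w(f'"""ODE system for model {sys.name!r}.')
    w("")
    w("Generated code: rhs(t, y[, stim]) returns the derivative vector;")
    w('initial_state(v0) gives the steady state at potential v0."""')
    w(_PRELUDE)
    if sys.reactions:
        w("import numpy as _np")
        w("")
    w("")
    w("STATE_INDEX = {" + ", ".join(f"{s!r}: {i}" for s, i in idx.items()) + "}")
    w(f"N_STATES = {len(states)}")
    w("")
    all_exprs = [e for _, _, e in sys.defs] + [e for _, e in sys.odes]
    all_exprs += [r.rhs for r in sys.relations]
    if uses_ghk(all_exprs):
        w("")
        w(_GHK)
    for rel in sys.relations:
        w("")
        w(f"def {rel.name}({', '.join(rel.formals)}):")
        w(f"    return {_py(rel.rhs)}")
        w("")
    w("")
    w("def rhs(t, y, stim=0.0):")
    for s in states:
        w(f"    {s} = y[{idx[s]}]")
    out.extend(_def_lines(sys.defs, "    "))
    w(f"    _dy = [0.0] * N_STATES")
    for s, e in sys.odes:
        w(f"    _dy[{idx[s]}] = {_py(e)}")
    w("    return _dy")
    w("")
    w("")
    _emit_currents(sys, w)
    w("")
    _emit_initial_state(sys, w)
    return "\n".join(out) + "\n"


def _emit_currents(sys: OdeSystem, w) -> None:
    w("def currents(t, y, stim=0.0):")
    w('    """Ionic current values at one trajectory point."""')
    for s in sys.states:
        w(f"    {s} = y[{sys.state_index[s]}]")
    for line in _def_lines(sys.defs, "    "):
        w(line)
    pairs = ", ".join(f"{c.i_name!r}: {c.i_name}" for c in sys.currents)
    w("    return {" + pairs + "}")
    w("")


def _emit_initial_state(sys: OdeSystem, w) -> None:
    # dependencies of every initialization expression
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
    defs, _rels, _needed = def_closure(sys, roots)
    state_set = set(sys.state_index)
    pre, post = split_state_dependent(defs, state_set)

    idx = sys.state_index
    w("def initial_state(v0=0.0):")
    w('    """Steady state of every gate/scheme at the given potential."""')
    w("    y0 = [0.0] * N_STATES")
    w("    t = 0.0")
    w("    stim = 0.0")
    w("    v = v0")
    w(f"    y0[{idx['v']}] = v" if "v" in idx else "    pass")
    for line in _def_lines(pre, "    "):
        w(line)
    for state, init in sys.init.items():
        if init[0] == "expr":
            w(f"    {state} = {_py(init[1])}")
            w(f"    y0[{idx[state]}] = {state}")
        elif init[0] == "zero" and state != "v":
            w(f"    {state} = 0.0")
    for line in _def_lines(post, "    "):
        w(line)
    for state, init in sys.init.items():
        if init[0] == "gate_ab":
            w(f"    _a = {_py(init[1])}")
            w(f"    _b = {_py(init[2])}")
            w(f"    {state} = _div(_a, _a + _b)")
            w(f"    y0[{idx[state]}] = {state}")
        elif init[0] == "gate_inftau":
            w(f"    {state} = {_py(init[1])}")
            w(f"    y0[{idx[state]}] = {state}")
    for r in sys.reactions:
        n = len(r.states)
        sidx = {s: i for i, s in enumerate(r.states)}
        w(f"    # steady state of kinetic scheme {r.name}")
        w(f"    _A = _np.zeros(({n + 1}, {n}))")
        for tr in r.transitions:
            w(f"    _f = {_py(tr.fwd)}")
            w(f"    _A[{sidx[tr.dst]}, {sidx[tr.src]}] += _f")
            w(f"    _A[{sidx[tr.src]}, {sidx[tr.src]}] -= _f")
            if tr.rev is not None:
                w(f"    _r = {_py(tr.rev)}")
                w(f"    _A[{sidx[tr.src]}, {sidx[tr.dst]}] += _r")
                w(f"    _A[{sidx[tr.dst]}, {sidx[tr.dst]}] -= _r")
        w(f"    _A[{n}, :] = 1.0")
        w(f"    _b = _np.zeros({n + 1})")
        w(f"    _b[{n}] = {format_number(r.conserve)}")
        w("    _sol = _np.linalg.lstsq(_A, _b, rcond=None)[0]")
        for s in r.states:
            w(f"    {s} = float(_sol[{sidx[s]}])")
            w(f"    y0[{idx[s]}] = {s}")
    w("    return y0")
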