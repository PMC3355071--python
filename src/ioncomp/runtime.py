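"""Reference numeric runtime for compiled systems.

The compiler's own integrator: it evaluates the ordered equation system by
tree-walking the expression ASTs (independently of any emitted code) and
integrates with a stiff-capable adaptive method from scipy.  Default
tolerances are rtol 1e-7 / atol 1e-9 — channel kinetics are stiff and the
conservation of kinetic-scheme occupancies is checked against these runs.

Steady-state initialization mirrors what simulation platforms do at t=0:
HH gates start at alpha/(alpha+beta) (equivalently inf(v0)), kinetic schemes
at the null-space of their rate matrix under the conservation constraint,
pools at their resting concentration, and v at the requested potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import EvaluationError, InitializationError, IntegrationError
from .expr import Num, eval_expr
from .odesystem import OdeSystem

__all__ = ["make_rhs", "steady_state_init", "simulate", "integrate_rhs",
           "SimResult", "clamp_system", "eval_outputs"]

DEFAULT_RTOL = 1e-7
DEFAULT_ATOL = 1e-9


def make_rhs(sys: OdeSystem, overrides: Optional[Dict[str, float]] = None
             ) -> Callable:
    """Build ``rhs(t, y) -> dy`` by direct evaluation of the ordered system."""
    overrides = overrides or {}
    relations = sys.relations_map()
    states = sys.states
    defs = sys.defs
    odes = sys.odes

    def rhs(t, y):
        bind = dict(zip(states, y))
        bind["t"] = t
        for name, kind, expr in defs:
            if name in overrides:
                bind[name] = overrides[name]
            else:
                bind[name] = eval_expr(expr, bind, relations)
        return [eval_expr(e, bind, relations) for _, e in odes]

    return rhs


class _InitBindings(dict):
    """Resolve parameters/assignments on demand during initialization.

    State variables are only visible once an earlier phase initialized them;
    requesting an uninitialized state (e.g. a conductance that depends on a
    gate) is an error, which keeps initialization well-founded.
    """

    def __init__(self, sys: OdeSystem):
        super().__init__()
        self._defs = {name: expr for name, _, expr in sys.defs}
        self._relations = sys.relations_map()
        self._states = set(sys.state_index)
        self._resolving = set()

    def __missing__(self, name):
        if name in self._states:
            raise EvaluationError(
                f"state {name!r} requested before it was initialized")
        if name not in self._defs:
            raise KeyError(name)
        if name in self._resolving:
            raise EvaluationError(f"circular definition of {name!r}")
        self._resolving.add(name)
        try:
            value = eval_expr(self._defs[name], self, self._relations)
        finally:
            self._resolving.discard(name)
        self[name] = value
        return value


def _reaction_steady_state(reaction, bind, relations) -> Dict[str, float]:
    states = list(reaction.states)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n + 1, n))
    for tr in reaction.transitions:
        f = eval_expr(tr.fwd, bind, relations)
        A[idx[tr.dst], idx[tr.src]] += f
        A[idx[tr.src], idx[tr.src]] -= f
        if tr.rev is not None:
            r = eval_expr(tr.rev, bind, relations)
            A[idx[tr.src], idx[tr.dst]] += r
            A[idx[tr.dst], idx[tr.dst]] -= r
    A[n, :] = 1.0
    b = np.zeros(n + 1)
    b[n] = reaction.conserve
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    if not np.all(np.isfinite(sol)):
        raise InitializationError(
            f"kinetic scheme {reaction.name!r}: singular steady-state system")
    residual = A @ sol - b
    if np.max(np.abs(residual)) > 1e-6 * max(1.0, np.max(np.abs(A))):
        raise InitializationError(
            f"kinetic scheme {reaction.name!r}: steady-state system is "
            f"inconsistent (residual {np.max(np.abs(residual)):.3g})")
    return {s: float(sol[idx[s]]) for s in states}


def steady_state_init(sys: OdeSystem, v0: float = 0.0,
                      overrides: Optional[Dict[str, float]] = None) -> np.ndarray:
    """Initial state vector with every channel at steady state for v = v0."""
    if not np.isfinite(v0):
        raise InitializationError("initial potential must be finite")
    bind = _InitBindings(sys)
    bind["v"] = float(v0)
    bind["t"] = 0.0
    bind.update(overrides or {})
    relations = sys.relations_map()
    values: Dict[str, float] = {"v": float(v0)}

    def set_state(name, value):
        values[name] = value
        bind[name] = value

    # phase 1: states with explicit/resting values (pools, fixed initials)
    for state, init in sys.init.items():
        if init[0] == "expr":
            set_state(state, eval_expr(init[1], bind, relations))
        elif init[0] == "zero":
            set_state(state, 0.0)
    # phase 2: HH gates (may read pool concentrations through assignments)
    for state, init in sys.init.items():
        if init[0] == "gate_ab":
            a = eval_expr(init[1], bind, relations)
            b = eval_expr(init[2], bind, relations)
            if a + b == 0:
                raise InitializationError(
                    f"gate {state!r}: alpha + beta = 0 at v0 = {v0}")
            set_state(state, a / (a + b))
        elif init[0] == "gate_inftau":
            set_state(state, eval_expr(init[1], bind, relations))
    # phase 3: kinetic schemes, jointly per scheme
    for reaction in sys.reactions:
        for s, val in _reaction_steady_state(reaction, bind, relations).items():
            set_state(s, val)

    y0 = np.zeros(sys.n_states)
    for state, i in sys.state_index.items():
        y0[i] = values.get(state, 0.0)
    return y0


@dataclass
class SimResult:
    """Trajectory: times x states, with helpers to evaluate derived outputs."""
    t: np.ndarray
    y: np.ndarray  # shape (len(t), n_states)
    sys: OdeSystem
    overrides: Dict[str, float]

    def state(self, name: str) -> np.ndarray:
        return self.y[:, self.sys.state_index[name]]

    def outputs(self, names: Sequence[str]) -> Dict[str, np.ndarray]:
        return eval_outputs(self.sys, self.t, self.y, names, self.overrides)

    def to_table(self, extra: Sequence[str] = ()) -> str:
        """Tab-separated table: time, states, then any derived outputs."""
        cols = ["t"] + self.sys.states + list(extra)
        data = [self.t] + [self.y[:, i] for i in range(self.y.shape[1])]
        if extra:
            outs = self.outputs(extra)
            data += [outs[n] for n in extra]
        lines = ["\t".join(cols)]
        for row in zip(*data):
            lines.append("\t".join(format(x, ".10g") for x in row))
        return "\n".join(lines) + "\n"


def integrate_rhs(rhs: Callable, y0, duration: float, dt: float = 0.025,
                  t0: float = 0.0, rtol: float = DEFAULT_RTOL,
                  atol: float = DEFAULT_ATOL, method: str = "LSODA"):
    """Integrate an arbitrary ``rhs(t, y)`` and sample on a regular grid."""
    n = max(2, int(round(duration / dt)) + 1)
    t_eval = t0 + np.linspace(0.0, duration, n)
    sol = solve_ivp(rhs, (t0, t0 + duration), np.asarray(y0, dtype=float),
                    method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    return sol.t, sol.y.T


def simulate(sys: OdeSystem, duration: float, dt: float = 0.025,
             y0=None, v0: float = 0.0, stim: Optional[float] = None,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             method: str = "LSODA") -> SimResult:
    """Simulate a compiled model with the reference integrator.

    ``stim`` is a constant injected current density (uA/cm^2) added to the
    membrane equation; ``v0`` sets the potential used for steady-state
    initialization when ``y0`` is not given.
    """
    overrides: Dict[str, float] = {}
    if stim is not None:
        overrides["stim"] = float(stim)
    if y0 is None:
        y0 = steady_state_init(sys, v0)
    rhs = make_rhs(sys, overrides)
    t, y = integrate_rhs(rhs, y0, duration, dt, rtol=rtol, atol=atol,
                         method=method)
    return SimResult(t=t, y=y, sys=sys, overrides=overrides)


def clamp_system(sys: OdeSystem) -> OdeSystem:
    """Copy of *sys* with the membrane equation replaced by dv/dt = 0.

    Nothing else changes: the diff of the two equation sets is exactly the
    membrane-potential equation.
    """
    odes = [(s, Num(0.0) if s == "v" else e) for s, e in sys.odes]
    init = dict(sys.init)
    init["v"] = ("voltage",)
    return replace(sys, odes=odes, init=init)


def eval_outputs(sys: OdeSystem, t: np.ndarray, y: np.ndarray,
                 names: Sequence[str],
                 overrides: Optional[Dict[str, float]] = None
                 ) -> Dict[str, np.ndarray]:
    """Evaluate parameters/assignments (e.g. currents) along a trajectory."""
    overrides = overrides or {}
    relations = sys.relations_map()
    states = sys.states
    wanted = set(names)
    out = {n: np.empty(len(t)) for n in names}
    for k in range(len(t)):
        bind = dict(zip(states, y[k]))
        bind["t"] = t[k]
        for name, kind, expr in sys.defs:
            if name in overrides:
                bind[name] = overrides[name]
            else:
                bind[name] = eval_expr(expr, bind, relations)
            if name in wanted:
                out[name][k] = bind[name]
    missing = wanted - {name for name, _, _ in sys.defs}
    for name in missing:
        if name in sys.state_index:
            out[name] = y[:, sys.state_index[name]]
        else:
            raise EvaluationError(f"no output named {name!r} in the system")
    return out
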