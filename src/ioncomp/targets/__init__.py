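"""Code generation targets: solver-API Python, Octave script, NMODL."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from ..errors import IoncompError
from ..odesystem import ModelInfo, OdeSystem, build_model_info
from ..sexpr import format_number
from .nmodl import emit_nmodl, read_nmodl_equations
from .octave import emit_octave_script
from .python_solver import emit_solver_function

__all__ = ["TARGETS", "emit", "emit_solver_function", "emit_octave_script",
           "emit_nmodl", "read_nmodl_equations", "emit_clamp_script"]

TARGETS = ("solver", "octave", "nmodl")


def emit(sys: OdeSystem, target: str = "solver",
         info: Optional[ModelInfo] = None, merge: bool = False,
         cfg=None) -> List[Tuple[str, str]]:
    """Emit code for *target*, as a list of (filename, text) pairs."""
    if target == "solver":
        return [(f"{sys.name}.py", emit_solver_function(sys))]
    if target == "octave":
        return [(f"{sys.name}.m", emit_octave_script(sys, cfg))]
    if target == "nmodl":
        return emit_nmodl(sys, info or build_model_info(sys), merge=merge)
    raise IoncompError(f"unknown code target {target!r}; choose from {TARGETS}")


def emit_clamp_script(sys: OdeSystem, protocol, target: str = "solver") -> str:
    """Standalone voltage-clamp script: clamped model plus sweep driver.

    The clamped variant replaces only the membrane-potential equation
    (dv/dt = 0); the driver holds v at the holding potential, steps to each
    command potential and records the clamped current.
    """
    from ..experiments import expand_clamp_steps
    from ..runtime import clamp_system

    clamped = clamp_system(sys)
    record = next((c.i_name for c in sys.currents if c.name == protocol.current),
                  None)
    if record is None:
        raise IoncompError(f"no current named {protocol.current!r} in the model")
    commands = expand_clamp_steps(protocol)
    if target in ("solver", "python"):
        return (emit_solver_function(clamped)
                + _python_clamp_driver(protocol, commands, record))
    if target == "octave":
        return (emit_octave_script(clamped, include_driver=False)
                + _octave_clamp_driver(clamped, protocol, commands, record))
    raise IoncompError(f"clamp scripts support solver/octave targets, "
                       f"not {target!r}")


def _python_clamp_driver(protocol, commands, record) -> str:
    cmd_list = ", ".join(format_number(c) for c in commands)
    return f'''

# --- voltage-clamp protocol for current {protocol.current} ---
HOLD = {format_number(protocol.hold)}
COMMANDS = [{cmd_list}]
HOLDING_DURATION = {format_number(protocol.holding_duration)}
BASE_DURATION = {format_number(protocol.base_duration)}
RECORD = {record!r}
V_INDEX = STATE_INDEX["v"]


def run_protocol(dt=0.025, rtol=1e-07, atol=1e-09):
    """One sweep per command potential: (command, t, recorded current)."""
    import numpy as np
    from scipy.integrate import solve_ivp

    def _grid(duration):
        return np.linspace(0.0, duration,
                           max(2, int(round(duration / dt)) + 1))

    sweeps = []
    y_hold = initial_state(HOLD)
    for command in COMMANDS:
        y0 = list(y_hold)
        y0[V_INDEX] = HOLD
        s1 = solve_ivp(rhs, (0.0, HOLDING_DURATION), y0, method="LSODA",
                       t_eval=_grid(HOLDING_DURATION), rtol=rtol, atol=atol)
        y1 = s1.y[:, -1].copy()
        y1[V_INDEX] = command
        s2 = solve_ivp(rhs, (0.0, BASE_DURATION), y1, method="LSODA",
                       t_eval=_grid(BASE_DURATION), rtol=rtol, atol=atol)
        t = np.concatenate([s1.t, HOLDING_DURATION + s2.t])
        y = np.hstack([s1.y, s2.y]).T
        i_rec = np.array([currents(tk, yk)[RECORD] for tk, yk in zip(t, y)])
        sweeps.append((command, t, i_rec))
    return sweeps


if __name__ == "__main__":
    for command, t, i_rec in run_protocol():
        peak = i_rec[abs(i_rec).argmax()]
        print(f"command {{command:8.2f}} mV  peak current {{peak:.6g}}")
'''


def _octave_clamp_driver(sys, protocol, commands, record) -> str:
    cmd_list = ", ".join(format_number(c) for c in commands)
    vi = sys.state_index["v"] + 1
    return f"""
%% --- voltage-clamp protocol for current {protocol.current} ---
hold_v = {format_number(protocol.hold)};
commands = [{cmd_list}];
hold_dur = {format_number(protocol.holding_duration)};
base_dur = {format_number(protocol.base_duration)};
y_hold = {sys.name}_init(hold_v);
for k = 1:numel(commands)
  y0 = y_hold;
  y0({vi}) = hold_v;
  [t1, y1] = ode15s(@{sys.name}_rhs, [0 hold_dur], y0);
  y0 = y1(end, :)';
  y0({vi}) = commands(k);
  [t2, y2] = ode15s(@{sys.name}_rhs, [0 base_dur], y0);
  t = [t1; hold_dur + t2];
  y = [y1; y2];
  printf("sweep %d command %g mV (%d points)\\n", k, commands(k), rows(y));
end
"""
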