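"""Simulation and voltage-clamp experiment components.

``simulation`` components carry the integration horizon and output step;
``voltage-clamp`` components describe a step protocol for one named ionic
current: hold the membrane at ``hold`` for ``holding-duration`` ms, then step
to a command potential for ``base-duration`` ms, with commands ascending from
``base`` in ``nsteps`` increments of ``stepsize`` mV (the usual I-V ladder).

A voltage-clamp component must name an existing ionic current of the model;
clamped systems replace only the membrane-potential equation, all channel
dynamics are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .components import (OHMIC_CURRENT, SIMULATION, VOLTAGE_CLAMP,
                         ComponentDecl, Model)
from .entities import PARAMETER
from .errors import StructuralError, ValidationError
from .expr import eval_expr
from .lower import build_component_env
from .odesystem import OdeSystem
from .runtime import (DEFAULT_ATOL, DEFAULT_RTOL, clamp_system, eval_outputs,
                      integrate_rhs, make_rhs, steady_state_init)

__all__ = ["SimConfig", "ClampProtocol", "ClampSweep", "build_sim_config",
           "build_clamp_protocol", "expand_clamp_steps", "run_clamp",
           "generate_clamp_script"]


@dataclass(frozen=True)
class SimConfig:
    duration: float   # ms
    stepsize: float   # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError("simulation duration must be positive")
        if self.stepsize <= 0:
            raise ValidationError("simulation stepsize must be positive")
        if self.stepsize >= self.duration:
            raise ValidationError("simulation stepsize must be below duration")


@dataclass(frozen=True)
class ClampProtocol:
    current: str            # name of the clamped ionic current component
    hold: float             # mV
    base: float             # mV
    stepsize: float         # mV
    nsteps: int
    holding_duration: float  # ms
    base_duration: float     # ms

    def __post_init__(self):
        if self.nsteps < 1:
            raise ValidationError("voltage clamp needs nsteps >= 1")
        if self.holding_duration <= 0 or self.base_duration <= 0:
            raise ValidationError("voltage clamp durations must be positive")


@dataclass
class ClampSweep:
    command: float
    t: np.ndarray
    v: np.ndarray
    current: np.ndarray


def _component_constants(comp: ComponentDecl) -> Dict[str, float]:
    env = build_component_env(comp)
    out = {}
    for name, ent in env.entities():
        if ent.kind == PARAMETER:
            out[name] = eval_expr(ent.rhs, {})
    return out


def _require(consts: Dict[str, float], name: str, what: str) -> float:
    if name not in consts:
        raise StructuralError(f"{what} component is missing constant {name!r}")
    return consts[name]


def build_sim_config(comp: ComponentDecl) -> SimConfig:
    if comp.ctype != SIMULATION:
        raise StructuralError(f"expected a simulation component, got {comp.ctype}")
    consts = _component_constants(comp)
    return SimConfig(duration=_require(consts, "duration", "simulation"),
                     stepsize=_require(consts, "stepsize", "simulation"))


def build_clamp_protocol(comp: ComponentDecl, model: Model) -> ClampProtocol:
    if comp.ctype != VOLTAGE_CLAMP:
        raise StructuralError(f"expected a voltage-clamp component, got {comp.ctype}")
    if comp.cname is None:
        raise StructuralError("voltage-clamp component must be named after a current")
    currents = [c.cname for c in model.root.children_of_type(OHMIC_CURRENT)]
    if comp.cname not in currents:
        raise StructuralError(
            f"voltage-clamp {comp.cname!r}: no ionic current component of "
            f"that name (model currents: {currents})")
    consts = _component_constants(comp)
    what = f"voltage-clamp {comp.cname}"
    return ClampProtocol(
        current=comp.cname,
        hold=_require(consts, "hold", what),
        base=_require(consts, "base", what),
        stepsize=_require(consts, "stepsize", what),
        nsteps=int(_require(consts, "nsteps", what)),
        holding_duration=_require(consts, "holding-duration", what),
        base_duration=_require(consts, "base-duration", what))


def expand_clamp_steps(protocol: ClampProtocol) -> List[float]:
    """Command potentials, ascending from base in stepsize increments."""
    return [protocol.base + k * protocol.stepsize for k in range(protocol.nsteps)]


def run_clamp(sys: OdeSystem, protocol: ClampProtocol, dt: float = 0.025,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
              ) -> List[ClampSweep]:
    """Simulate the protocol with the reference integrator.

    Each sweep holds v at ``hold`` (channels pre-equilibrated there), then
    steps to the command potential; the named current is recorded throughout.
    """
    record = next((c.i_name for c in sys.currents if c.name == protocol.current),
                  None)
    if record is None:
        raise StructuralError(
            f"compiled system has no current named {protocol.current!r}")
    clamped = clamp_system(sys)
    rhs = make_rhs(clamped)
    vi = clamped.state_index["v"]
    y_hold = steady_state_init(sys, protocol.hold)
    sweeps = []
    for command in expand_clamp_steps(protocol):
        y0 = y_hold.copy()
        y0[vi] = protocol.hold
        t1, y1 = integrate_rhs(rhs, y0, protocol.holding_duration, dt,
                               rtol=rtol, atol=atol)
        y0 = y1[-1].copy()
        y0[vi] = command
        t2, y2 = integrate_rhs(rhs, y0, protocol.base_duration, dt,
                               t0=protocol.holding_duration, rtol=rtol, atol=atol)
        t = np.concatenate([t1, t2])
        y = np.vstack([y1, y2])
        cur = eval_outputs(clamped, t, y, [record])[record]
        sweeps.append(ClampSweep(command=command, t=t, v=y[:, vi], current=cur))
    return sweeps


def generate_clamp_script(protocol: ClampProtocol, sys: OdeSystem,
                          target: str = "solver") -> str:
    """Emit a standalone script running the protocol on a code target."""
    from .targets import emit_clamp_script  # local import: targets layer
    return emit_clamp_script(sys, protocol, target)
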