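"""Lowering of biophysical concepts to equations.

Each function here maps one modeling concept to the entities that represent
it in the equation layer:

* HH-style gates become first-order rate equations,
  ``dm/dt = alpha(v) (1-m) - beta(v) m`` or ``dm/dt = (m_inf - m)/tau_m``;
* Markov kinetic schemes become one mass-action ODE per state, with the
  occupancy total conserved by construction;
* Ohmic currents become ``g = gbar * prod(gate^power)`` and
  ``i = g * (v - e_rev)``;
* GHK currents become ``i = pmax * prod(gate^power) * ghk(v, ci, co, z, celsius)``;
* a decaying pool becomes ``dCa/dt = -B * i_src - (Ca - steady)/tau``;
* the membrane equation collects every current:
  ``dv/dt = (stim - sum(i)) / C`` (``stim`` is an injected current density
  parameter, 0 by default).

Names passed in are already resolved (the caller mangles component paths);
these functions only build expressions and entities.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

from .entities import ASSIGNMENT, RATE, REACTION, Entity
from .errors import StructuralError, ValidationError
from .expr import Apply, Binary, Expr, Neg, Num, Sym
from .ghk import ghk_flux  # re-exported: part of this layer's surface

__all__ = [
    "ghk_flux", "gate_power_expr", "conductance_product", "expand_hh_gating",
    "expand_reaction", "assemble_ohmic_current", "assemble_ghk_current",
    "expand_decaying_pool", "assemble_membrane_potential",
]

V = Sym("v")


def _product(factors: Sequence[Expr]) -> Expr:
    out = factors[0]
    for f in factors[1:]:
        out = Binary("*", out, f)
    return out


def _sum(terms: Sequence[Expr]) -> Expr:
    out = terms[0]
    for t in terms[1:]:
        out = Binary("+", out, t)
    return out


def gate_power_expr(state: str, power: int) -> Expr:
    if power < 1:
        raise ValidationError(f"gate {state!r}: power must be >= 1, got {power}")
    return Sym(state) if power == 1 else Binary("^", Sym(state), Num(power))


def conductance_product(gates: Sequence[Tuple[str, int]]) -> Optional[Expr]:
    """``prod(gate^power)`` over (state name, power) pairs; None for no gates."""
    if not gates:
        return None
    return _product([gate_power_expr(s, p) for s, p in gates])


def expand_hh_gating(gate) -> Entity:
    """RATE entity for one HH gate (``GateSpec`` from the component layer)."""
    if gate.power < 1:
        raise ValidationError(f"gate {gate.name!r}: power must be >= 1")
    m = Sym(gate.name)
    if gate.rate_form == "ab":
        # dm/dt = alpha(v) * (1 - m) - beta(v) * m
        rhs = Binary("-",
                     Binary("*", gate.fwd, Binary("-", Num(1.0), m)),
                     Binary("*", gate.rev, m))
        init = ("gate_ab", gate.fwd, gate.rev)
    else:
        # dm/dt = (m_inf(v) - m) / tau_m(v)
        rhs = Binary("/", Binary("-", gate.inf, m), gate.tau)
        init = ("gate_inftau", gate.inf, gate.tau)
    if gate.initial is not None:
        init = ("expr", Num(float(gate.initial)))
    return Entity(name=gate.name, kind=RATE, state=gate.name, rhs=rhs, init=init)


def expand_reaction(reaction: Entity) -> List[Entity]:
    """One mass-action RATE entity per state of a kinetic scheme.

    The per-state inflow/outflow terms cancel pairwise over the whole scheme,
    so the occupancy total is a conserved quantity of the emitted ODEs.
    """
    if reaction.kind != REACTION:
        raise TypeError("expand_reaction expects a REACTION entity")
    terms = {s: [] for s in reaction.states}
    for tr in reaction.transitions:
        flow = Binary("*", tr.fwd, Sym(tr.src))
        terms[tr.src].append(Neg(flow))
        terms[tr.dst].append(flow)
        if tr.rev is not None:
            back = Binary("*", tr.rev, Sym(tr.dst))
            terms[tr.dst].append(Neg(back))
            terms[tr.src].append(back)
    out = []
    for s in reaction.states:
        rhs = _sum(terms[s]) if terms[s] else Num(0.0)
        out.append(Entity(name=s, kind=RATE, state=s, rhs=rhs,
                          init=("reaction", reaction.name)))
    return out


def assemble_ohmic_current(name_g: str, name_i: str, gbar: str, e_rev: str,
                           gates: Sequence[Tuple[str, int]]) -> List[Entity]:
    """``g = gbar * prod(gates)`` and ``i = g * (v - e_rev)``."""
    prod = conductance_product(gates)
    g_rhs = Sym(gbar) if prod is None else Binary("*", Sym(gbar), prod)
    i_rhs = Binary("*", Sym(name_g), Binary("-", V, Sym(e_rev)))
    return [Entity(name=name_g, kind=ASSIGNMENT, rhs=g_rhs),
            Entity(name=name_i, kind=ASSIGNMENT, rhs=i_rhs)]


def assemble_ghk_current(name_i: str, pmax: str, gates: Sequence[Tuple[str, int]],
                         ci: Expr, co: Expr, valence: int,
                         celsius: str = "celsius") -> List[Entity]:
    """``i = pmax * prod(gates) * ghk(v, ci, co, z, celsius)``."""
    if valence == 0:
        raise ValidationError("GHK current requires a nonzero valence")
    flux = Apply("ghk", (V, ci, co, Num(float(valence)), Sym(celsius)))
    factors = [Sym(pmax)]
    prod = conductance_product(gates)
    if prod is not None:
        factors.append(prod)
    factors.append(flux)
    return [Entity(name=name_i, kind=ASSIGNMENT, rhs=_product(factors))]


def expand_decaying_pool(out_name: str, B: str, steady: str, tau: str,
                         current_names: Sequence[str]) -> Entity:
    """Traub-style decay: ``dCa/dt = -B * i_src - (Ca - steady) / tau``."""
    if not current_names:
        raise StructuralError("decaying pool has no source current")
    i_total = _sum([Sym(n) for n in current_names])
    rhs = Binary("-",
                 Neg(Binary("*", Sym(B), i_total)),
                 Binary("/", Binary("-", Sym(out_name), Sym(steady)), Sym(tau)))
    return Entity(name=out_name, kind=RATE, state=out_name, rhs=rhs,
                  init=("expr", Sym(steady)))


def assemble_membrane_potential(current_names: Sequence[str], capacitance: str,
                                stim: str = "stim") -> Entity:
    """``dv/dt = (stim - sum(currents)) / C``."""
    if not current_names:
        raise StructuralError("model has no ionic currents")
    rhs = Binary("/",
                 Binary("-", Sym(stim), _sum([Sym(n) for n in current_names])),
                 Sym(capacitance))
    return Entity(name="v", kind=RATE, state="v", rhs=rhs, init=("voltage",))
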