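"""Built-in model sources: HH, a Purkinje-neuron model, random models.

``hh_fixture`` is the classic Hodgkin-Huxley squid-axon model in the shifted
convention (rest at 0 mV, E_Na = 115 mV, depolarization positive), written
in the compact current syntax.

``kr_fixture`` is a Purkinje-neuron model of the Khaliq-Raman (2003) family,
reconstructed from the published model literature: the 13-state resurgent
sodium kinetic scheme (Raman-Bean topology and rate constants), a P-type
calcium current using the GHK constant-field equation wired to a Traub-style
decaying calcium pool, and a calcium-and-voltage-gated BK potassium current
that is the target of the standard voltage-clamp protocol.  It is a
reconstruction for exercising every language feature, not a validated
transcription of the original published parameter set.

``random_model`` draws structurally valid models from bounded, numerically
safe rate families (sigmoid/exponential/constant) for property testing.
"""

from __future__ import annotations

import random

__all__ = ["hh_fixture", "kr_fixture", "random_model"]

_HH = """\
;; Hodgkin-Huxley squid axon model (shifted convention: rest at 0 mV).
(Membrane-potential hh
 (Membrane-capacitance 1.0 uF/cm*cm)
 (Ohmic-current Na (E = 115 mV) (g_max = 120 mS/cm*cm)
  (gating m (power 3)
   (forward-rate (2.5 - 0.1*V)/((exp (2.5 - 0.1*V)) - 1))
   (reverse-rate (0.125 * exp(-V/80))))
  (gating h (power 1)
   (forward-rate (0.07 * exp(-V/20)))
   (reverse-rate 1/((exp (3 - 0.1*V)) + 1)))
 ) ;; end of Ohmic-current Na
 (Ohmic-current K (E = -12 mV) (g_max = 36 mS/cm*cm)
  (gating n (power 4)
   (forward-rate (0.1 - 0.01*V)/((exp (1 - 0.1*V)) - 1))
   (reverse-rate (0.125 * exp(-V/80))))
 ) ;; end of Ohmic-current K
 (Ohmic-current Leak (E = 10.613 mV) (g_max = 0.3 mS/cm*cm))
) ;; end of Membrane-potential

(simulation (out duration stepsize)
 (const duration = 2000)
 (const stepsize = 1e-4)
)
"""

_KR = """\
;; Purkinje neuron model, Khaliq-Raman (2003) family (reconstruction).
(Membrane-potential kr
 (Membrane-capacitance 0.9 uF/cm*cm)
 (input (cai from decaying-pool ca))

 ;; resurgent sodium current: 13-state Raman-Bean kinetic scheme
 (Ohmic-current Narsg (g_max = 16 mS/cm*cm)
  (permeating-ion (name na) (out e) (const e = 60 mV))
  (gating (out O)
   (const Con = 0.005)
   (const Coff = 0.5)
   (const Oon = 0.75)
   (const Ooff = 0.005)
   (const aS = (0.75 / 0.005) ^ 0.25)
   (const bS = (0.005 / 0.5) ^ 0.25)
   (const gamma = 150)
   (const delta = 40)
   (const epsilon = 1.75)
   (alfa = 150 * exp(V / 20))
   (beta = 3 * exp(-V / 20))
   (zeta = 0.03 * exp(-V / 25))
   (reaction z
    (transitions
     (<-> C1 C2 (4 * alfa) beta)
     (<-> C2 C3 (3 * alfa) (2 * beta))
     (<-> C3 C4 (2 * alfa) (3 * beta))
     (<-> C4 C5 alfa (4 * beta))
     (<-> C5 O gamma delta)
     (<-> O B epsilon zeta)
     (<-> O I6 Oon Ooff)
     (<-> C1 I1 Con Coff)
     (<-> C2 I2 (Con * aS) (Coff * bS))
     (<-> C3 I3 (Con * aS^2) (Coff * bS^2))
     (<-> C4 I4 (Con * aS^3) (Coff * bS^3))
     (<-> C5 I5 (Con * aS^4) (Coff * bS^4))
     (<-> I5 I6 gamma delta))
    (conserve 1)
    (open O (power 1)))))

 ;; P-type calcium current (GHK constant-field law, reads cai from the pool)
 (Ohmic-current CaP
  (hh-gating-dynamics (out m)
   (m_inf = 1 / (1 + exp(-(V + 19) / 5.5)))
   (tau_m = 1 / (5 * (exp((V + 6) / 12) + exp(-(V + 6) / 12)))))
  (permeability (out pmax)
   (const pmax = 6e-5))
  (permeating-ion (name ca) (valence 2)
   (const co = 2.4)))

 ;; calcium- and voltage-activated BK potassium current
 (Ohmic-current CaBK (g_max = 14 mS/cm*cm)
  (permeating-ion (name k) (out e) (const e = -88 mV))
  (hh-gating-dynamics (out m z)
   (power m 3)
   (power z 2)
   (m_inf = 1 / (1 + exp(-(V + 28.9) / 6.2)))
   (tau_m = 0.000505 + 1 / (exp((V + 86.4) / 10.1) + exp(-(V - 33.3) / 10)))
   (z_inf = 1 / (1 + 0.001 / cai))
   (tau_z = 1.0)))

 ;; leak
 (Ohmic-current Lkg (E = -60 mV) (g_max = 9e-2 mS/cm*cm))

 ;; calcium concentration dynamics (Traub-style decaying pool)
 (decaying-pool (name ca) (out cac)
  (current CaP)
  (const B = 0.01)
  (const steady = 1e-4)
  (const tau = 1.0))
)

(simulation (out duration stepsize)
 (const duration = 2000)
 (const stepsize = 1e-4)
)

(voltage-clamp (name CaBK)
 (out hold base stepsize nsteps holding-duration base-duration)
 (const hold = -90)
 (const base = -40)
 (const stepsize = 10)
 (const nsteps = 5)
 (const holding-duration = 5)
 (const base-duration = 20)
)
"""


def hh_fixture() -> str:
    """Model source for the Hodgkin-Huxley fixture (plus simulation block)."""
    return _HH


def kr_fixture() -> str:
    """Model source for the Purkinje-neuron (Khaliq-Raman family) fixture."""
    return _KR


def _num(x: float) -> str:
    return format(x, ".6g")


def _rate(rng: random.Random) -> str:
    """A numerically safe voltage-dependent rate expression."""
    family = rng.choice(["sigmoid", "expo", "const"])
    a = _num(10 ** rng.uniform(-1.5, 0.7))
    b = _num(rng.uniform(5.0, 20.0))
    c = _num(rng.uniform(-60.0, 40.0))
    if family == "sigmoid":
        return f"({a} / (1 + exp(-(V - {c}) / {b})))"
    if family == "expo":
        scale = _num(rng.uniform(25.0, 80.0) * rng.choice([-1.0, 1.0]))
        return f"({a} * exp((V - {c}) / {scale}))"
    return a


def _gate_block(rng: random.Random, gname: str) -> str:
    power = rng.randint(1, 4)
    if rng.random() < 0.5:
        return (f"  (gating {gname} (power {power})\n"
                f"   (forward-rate {_rate(rng)})\n"
                f"   (reverse-rate {_rate(rng)}))\n")
    return (f"  (gating (out {gname}) (power {gname} {power})\n"
            f"   (d ({gname}) = ({_rate(rng)}) * (1 - {gname})"
            f" - ({_rate(rng)}) * {gname}))\n")


def _scheme_block(rng: random.Random, k: int) -> str:
    n = rng.randint(2, 4)
    states = [f"S{k}x{j}" for j in range(n - 1)] + [f"O{k}"]
    lines = []
    for a, b in zip(states[:-1], states[1:]):
        lines.append(f"     (<-> {a} {b} {_rate(rng)} {_rate(rng)})")
    return (f"  (gating (out O{k})\n"
            f"   (reaction z{k}\n"
            f"    (transitions\n" + "\n".join(lines) + ")\n"
            f"    (conserve 1)\n"
            f"    (open O{k} (power {rng.randint(1, 2)}))))\n")


_E_RANGE = {"na": (40.0, 120.0), "k": (-100.0, -60.0), "ca": (80.0, 140.0)}


def random_model(seed: int, n_currents: int = 2) -> str:
    """A structurally valid random model; same seed, same text."""
    if n_currents < 1:
        raise ValueError("n_currents must be >= 1")
    rng = random.Random(seed)
    parts = [f";; random model (seed {seed})",
             f"(Membrane-potential rnd{seed % 100000}",
             " (Membrane-capacitance 1.0 uF/cm*cm)"]
    for k in range(n_currents):
        species = rng.choice(["na", "k", "ca"])
        ghk = species == "ca" and rng.random() < 0.5
        name = f"I{k}{species}"
        gates = []
        if rng.random() < 0.2:
            gates.append(_scheme_block(rng, k))
        else:
            for j in range(rng.randint(1, 2)):
                gates.append(_gate_block(rng, f"g{k}x{j}"))
        body = "".join(gates)
        if ghk:
            pmax = _num(10 ** rng.uniform(-6.0, -4.0))
            ci = _num(10 ** rng.uniform(-5.0, -3.0))
            co = _num(rng.uniform(1.0, 3.0))
            parts.append(
                f" (Ohmic-current {name}\n{body}"
                f"  (permeability (out pmax) (const pmax = {pmax}))\n"
                f"  (permeating-ion (name ca) (valence 2)\n"
                f"   (const ci = {ci})\n"
                f"   (const co = {co})))")
        else:
            lo, hi = _E_RANGE[species]
            e = _num(rng.uniform(lo, hi))
            gbar = _num(10 ** rng.uniform(-2.0, 1.7))
            parts.append(
                f" (Ohmic-current {name}\n{body}"
                f"  (pore (out gbar) (const gbar = {gbar}))\n"
                f"  (permeating-ion (name {species}) (out e) (const e = {e})))")
    if rng.random() < 0.5:
        e = _num(rng.uniform(-80.0, 20.0))
        g = _num(10 ** rng.uniform(-4.0, -1.0))
        parts.append(f" (Ohmic-current Background (E = {e} mV) (g_max = {g}))")
    parts.append(")")
    return "\n".join(parts) + "\n"
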