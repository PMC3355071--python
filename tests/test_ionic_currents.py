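"""Biophysics lowering: GHK flux, gates, kinetic schemes, pools, membrane."""

import math

import numpy as np
import pytest

from ioncomp import compile_model
from ioncomp.currents import expand_reaction, ghk_flux
from ioncomp.entities import build_entity
from ioncomp.errors import ValidationError
from ioncomp.expr import eval_expr, free_vars
from ioncomp.ghk import FARADAY
from ioncomp.runtime import simulate, steady_state_init
from ioncomp.sexpr import parse_sexpr


class TestGhkFlux:
    def test_zero_voltage_limit(self):
        """V -> 0 limit equals z F (ci - co) per unit permeability."""
        ci, co, z = 1e-4, 2.4, 2
        expected = z * FARADAY * (ci - co)
        got = ghk_flux(0.0, ci, co, z)
        assert got == pytest.approx(expected, rel=1e-6)
        # and the limit is approached smoothly from either side
        for v in (1e-7, -1e-7):
            assert ghk_flux(v, ci, co, z) == pytest.approx(expected, rel=1e-4)

    def test_symmetric_concentrations_linear_in_v(self):
        """ci = co makes the flux exactly linear in V (Ohmic-like, E = 0)."""
        c, z = 1.0, 2
        base = ghk_flux(10.0, c, c, z)
        for v in (-80.0, -25.0, 5.0, 40.0, 120.0):
            assert ghk_flux(v, c, c, z) == pytest.approx(base * v / 10.0,
                                                         rel=1e-9)

    def test_inward_sign_when_internal_depleted(self):
        assert ghk_flux(10.0, 0.0, 2.0, 2) < 0.0

    def test_zero_valence_rejected(self):
        with pytest.raises(ValidationError):
            ghk_flux(0.0, 1.0, 1.0, 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            ghk_flux(0.0, -1.0, 1.0, 2)


def _tiny_model(current_block, extra=""):
    return f"""(Membrane-potential tiny
 (Membrane-capacitance 1.0 uF/cm*cm)
 {current_block}
 {extra})"""


class TestOhmicAssembly:
    def test_current_is_zero_at_reversal(self, hh_compiled):
        sys = hh_compiled.sys
        defs = {n: e for n, _, e in sys.defs}
        bind = {"v": 115.0, "Na_gating_m": 0.7, "Na_gating_2_h": 0.3,
                "K_gating_n": 0.2, "t": 0.0}
        for n, _, e in sys.defs:
            bind[n] = eval_expr(e, bind) if n not in bind else bind[n]
        assert bind["Na_i"] == pytest.approx(0.0, abs=1e-12)

    def test_open_gates_give_maximal_conductance(self, hh_compiled):
        sys = hh_compiled.sys
        bind = {"v": 0.0, "Na_gating_m": 1.0, "Na_gating_2_h": 1.0,
                "K_gating_n": 1.0, "t": 0.0}
        for n, _, e in sys.defs:
            bind[n] = eval_expr(e, bind) if n not in bind else bind[n]
        assert bind["Na_g"] == pytest.approx(120.0)
        assert bind["K_g"] == pytest.approx(36.0)

    def test_na_conductance_uses_m3h(self, hh_compiled):
        sys = hh_compiled.sys
        g = {n: e for n, _, e in sys.defs}["Na_g"]
        m, h = 0.4, 0.6
        got = eval_expr(g, {"Na_gating_m": m, "Na_gating_2_h": h,
                            "Na_pore_gbar": 120.0})
        assert got == pytest.approx(120.0 * m ** 3 * h, rel=1e-12)


class TestReactions:
    def _scheme(self, text):
        return build_entity(parse_sexpr(text))

    def test_two_state_equal_rates_steady_half(self):
        src = _tiny_model("""(Ohmic-current Na
          (gating (out O)
           (reaction r (transitions (<-> C O 3 3)) (conserve 1) (open O)))
          (pore (out gbar) (const gbar = 1))
          (permeating-ion (name na) (out e) (const e = 50)))""")
        sys = compile_model(src).sys
        y0 = steady_state_init(sys, 0.0)
        occ = {s: y0[sys.state_index[s]] for s in sys.reactions[0].states}
        assert list(occ.values()) == pytest.approx([0.5, 0.5])

    def test_detailed_balance_three_to_one(self):
        src = _tiny_model("""(Ohmic-current Na
          (gating (out O)
           (reaction r (transitions (<-> C O 3 1)) (conserve 1) (open O)))
          (pore (out gbar) (const gbar = 1))
          (permeating-ion (name na) (out e) (const e = 50)))""")
        sys = compile_model(src).sys
        y0 = steady_state_init(sys, 0.0)
        occ = [y0[sys.state_index[s]] for s in sys.reactions[0].states]
        assert occ == pytest.approx([0.25, 0.75])

    def test_13_state_scheme_emits_13_states(self, kr_compiled):
        (scheme,) = kr_compiled.sys.reactions
        assert len(scheme.states) == 13

    def test_emitted_rates_sum_to_zero(self, kr_compiled):
        """Mass-action inflows/outflows cancel: d/dt of the occupancy total
        is identically zero at random state values."""
        rng = np.random.default_rng(3)
        (scheme,) = kr_compiled.sys.reactions
        entities = expand_reaction(scheme)
        for _ in range(20):
            bind = {s: rng.uniform(0, 1) for s in scheme.states}
            bind["v"] = rng.uniform(-90, 40)
            names = set()
            for ent in entities:
                names |= free_vars(ent.rhs)
            for n in names:
                bind.setdefault(n, rng.uniform(0.01, 2.0))
            total = sum(eval_expr(ent.rhs, bind) for ent in entities)
            assert abs(total) < 1e-10 * max(1.0, *(abs(bind[s]) for s in scheme.states)) * 1e3


class TestDecayingPool:
    POOL = _tiny_model(
        """(Ohmic-current Lk (E = -65 mV) (g_max = 0.2))""",
        """(decaying-pool (name ca) (out cac)
            (current Lk)
            (const B = 0.05) (const steady = 1e-4) (const tau = 2.0))""")

    def test_exponential_relaxation_with_zero_current(self):
        """With the source current at zero (v held at its reversal), the
        concentration relaxes to `steady` with time constant tau."""
        from ioncomp.runtime import clamp_system, make_rhs, integrate_rhs
        sys = compile_model(self.POOL).sys
        clamped = clamp_system(sys)
        y0 = np.zeros(sys.n_states)
        y0[sys.state_index["v"]] = -65.0       # reversal -> i = 0
        ca0 = 5e-3
        y0[sys.state_index["ca_cac"]] = ca0
        t, y = integrate_rhs(make_rhs(clamped), y0, duration=4.0, dt=0.5)
        steady, tau = 1e-4, 2.0
        expected = steady + (ca0 - steady) * np.exp(-t / tau)
        assert y[:, sys.state_index["ca_cac"]] == pytest.approx(expected,
                                                                rel=1e-5)

    def test_fixed_point_under_constant_current(self):
        """Constant source current i: fixed point is steady - B i tau
        (solve -B i - (c - steady)/tau = 0)."""
        from ioncomp.runtime import clamp_system, make_rhs, integrate_rhs
        sys = compile_model(self.POOL).sys
        clamped = clamp_system(sys)
        v_hold = -75.0                          # i = 0.2 * (v + 65) = -2
        i_const = 0.2 * (v_hold + 65.0)
        y0 = np.zeros(sys.n_states)
        y0[sys.state_index["v"]] = v_hold
        y0[sys.state_index["ca_cac"]] = 1e-4
        t, y = integrate_rhs(make_rhs(clamped), y0, duration=40.0, dt=5.0)
        fixed = 1e-4 - 0.05 * i_const * 2.0
        assert y[-1, sys.state_index["ca_cac"]] == pytest.approx(fixed,
                                                                 rel=1e-6)

    def test_exported_concentration_reaches_ghk_current(self, kr_compiled):
        sys = kr_compiled.sys
        (cap,) = [c for c in sys.currents if c.law == "ghk"]
        i_expr = {n: e for n, _, e in sys.defs}[cap.i_name]
        assert "cai" in free_vars(i_expr)


class TestMembranePotential:
    def test_hh_membrane_equation_collects_all_currents(self, hh_compiled):
        sys = hh_compiled.sys
        v_rhs = dict(sys.odes)["v"]
        fv = free_vars(v_rhs)
        assert {"Na_i", "K_i", "Leak_i", "membrane_capacitance_C",
                "stim"} <= fv

    def test_leak_only_at_reversal_is_stationary(self):
        src = _tiny_model("(Ohmic-current Leak (E = 10.613 mV) (g_max = 0.3))")
        sys = compile_model(src).sys
        res = simulate(sys, duration=5.0, dt=0.5, v0=10.613)
        assert res.state("v") == pytest.approx(np.full(11, 10.613), abs=1e-9)

    def test_mixed_ohmic_and_ghk_sum(self, kr_compiled):
        v_rhs = dict(kr_compiled.sys.odes)["v"]
        fv = free_vars(v_rhs)
        assert {"Narsg_i", "CaP_i", "CaBK_i", "Lkg_i"} <= fv
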