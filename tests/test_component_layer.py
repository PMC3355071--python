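"""Component structure, flattening and input wiring."""

import pytest
from hypothesis import given, settings, strategies as st

from ioncomp import compile_model, fixtures
from ioncomp.components import read_model, validate_structure
from ioncomp.entities import ASSIGNMENT
from ioncomp.errors import (AmbiguityError, OutputContractError,
                            StructuralError, UnresolvedReferenceError,
                            WiringError)
from ioncomp.expr import Sym, eval_expr, free_vars
from ioncomp.lower import build_component_env, flatten, lower_model
from ioncomp.odesystem import build_ode_system, order_entities
from ioncomp.sexpr import parse_sexpr


def _compile(src):
    return compile_model(src)


MINIMAL = """
(Membrane-potential m1
 (Membrane-capacitance 1.0 uF/cm*cm)
 (Ohmic-current Leak (E = -65 mV) (g_max = 0.1 mS/cm*cm)))
"""


class TestComponentEnv:
    def test_pore_with_output(self):
        env = build_component_env(
            read_model(MINIMAL).root.children[1].children[1])
        # desugared pore exports gbar
        assert env.ctype == "pore" and env.outputs == ["gbar"]

    def test_missing_output_is_contract_error(self):
        from ioncomp.components import parse_component
        comp = parse_component(parse_sexpr("(pore (out gbar))"))
        with pytest.raises(OutputContractError, match="gbar"):
            build_component_env(comp)

    def test_template_requires_exact_names(self):
        from ioncomp.components import parse_component
        comp = parse_component(parse_sexpr(
            "(hh-gating-dynamics (out m) (m_inf = 0.5))"))
        with pytest.raises(StructuralError, match="tau_m"):
            build_component_env(comp)

    def test_kr_components_match_expected_set(self, kr_compiled):
        root = kr_compiled.model.root
        types = sorted(c.ctype for c in root.children)
        assert types == ["decaying-pool", "membrane-capacitance",
                         "ohmic-current", "ohmic-current", "ohmic-current",
                         "ohmic-current"]


class TestStructureRules:
    def test_minimal_model_passes(self):
        validate_structure(read_model(MINIMAL))

    def test_missing_capacitance_rejected(self):
        src = "(Membrane-potential m (Ohmic-current Leak (E = 0 mV) (g_max = 1)))"
        with pytest.raises(StructuralError, match="capacitance"):
            validate_structure(read_model(src))

    def test_no_currents_rejected(self):
        src = "(Membrane-potential m (Membrane-capacitance 1.0 uF/cm*cm))"
        with pytest.raises(StructuralError, match="current"):
            validate_structure(read_model(src))

    def test_current_without_pore_rejected(self):
        src = """(Membrane-potential m
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (Ohmic-current Na
                   (gating m (power 1) (forward-rate 1) (reverse-rate 1))
                   (permeating-ion (name na) (out e) (const e = 50))))"""
        with pytest.raises(StructuralError, match="pore"):
            validate_structure(read_model(src))

    def test_ion_specific_current_needs_gating(self):
        src = """(Membrane-potential m
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (Ohmic-current Na (E = 50 mV) (g_max = 1)))"""
        with pytest.raises(StructuralError, match="gating"):
            validate_structure(read_model(src))

    def test_ghk_needs_valence(self):
        src = """(Membrane-potential m
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (Ohmic-current CaX
                   (gating m (power 1) (forward-rate 1) (reverse-rate 1))
                   (permeability (out pmax) (const pmax = 1e-5))
                   (permeating-ion (name ca) (const ci = 1e-4) (const co = 2))))"""
        with pytest.raises(StructuralError, match="valence"):
            validate_structure(read_model(src))


TWO_GATING = """
(Membrane-potential m2
 (Membrane-capacitance 1.0 uF/cm*cm)
 (Ohmic-current Na (E = 115 mV) (g_max = 120)
  (gating m (power 3) (forward-rate 1) (reverse-rate 2))
  (gating h (power 1) (forward-rate 3) (reverse-rate 4)))
 (Ohmic-current K (E = -12 mV) (g_max = 36)
  (gating m (power 4) (forward-rate 5) (reverse-rate 6))))
"""


class TestFlatten:
    def test_sibling_gates_get_distinct_names(self):
        sys = _compile(TWO_GATING).sys
        states = set(sys.state_index)
        # two different components both define `m`; names stay distinct
        assert len([s for s in states if s.endswith("_m")]) == 2
        assert len(states) == len(sys.state_index)

    def test_inner_reference_to_outer_parameter(self):
        src = """(Membrane-potential m3
                  (const scale = 2)
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (Ohmic-current Leak (E = -65 mV) (g_max = 0.1))
                  (Ohmic-current Na
                   (gating m (power 1) (forward-rate (scale * 1)) (reverse-rate 1))
                   (pore (out gbar) (const gbar = 10))
                   (permeating-ion (name na) (out e) (const e = 50))))"""
        sys = _compile(src).sys
        (rate,) = [e for s, e in sys.odes if s.endswith("_m")]
        assert "scale" in free_vars(rate)  # resolved to the root-level name

    def test_unresolved_reference_is_error(self):
        src = """(Membrane-potential m4
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (Ohmic-current Na
                   (gating m (power 1) (forward-rate (mystery * 1)) (reverse-rate 1))
                   (pore (out gbar) (const gbar = 10))
                   (permeating-ion (name na) (out e) (const e = 50))))"""
        with pytest.raises(UnresolvedReferenceError, match="mystery"):
            _compile(src)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000), n=st.integers(1, 4))
    def test_flattening_collision_free(self, seed, n):
        sys = _compile(fixtures.random_model(seed, n)).sys
        names = list(sys.state_index) + [n_ for n_, _, _ in sys.defs] \
            + [r.name for r in sys.relations]
        assert len(names) == len(set(names))

    def test_flattening_preserves_evaluation(self):
        """Rate expressions evaluate identically before and after flattening
        (component-local names vs path-prefixed names)."""
        import math
        src = TWO_GATING
        model = read_model(src)
        sys = _compile(src).sys
        # forward/reverse constants make dm/dt = f*(1-m) - r*m checkable
        for s, e in sys.odes:
            if s.endswith("Na_gating_m"):
                for m in (0.0, 0.25, 1.0):
                    assert eval_expr(e, {s: m}) == pytest.approx(
                        1.0 * (1 - m) - 2.0 * m, rel=1e-12)


class TestInputWiring:
    def test_pool_output_wired_to_cai(self, kr_compiled):
        sys = kr_compiled.sys
        wiring = [(n, e) for n, k, e in sys.defs
                  if n == "cai" and k == ASSIGNMENT]
        assert wiring == [("cai", Sym("ca_cac"))]

    def test_wiring_to_missing_component_is_error(self):
        src = MINIMAL.replace(
            "(Membrane-capacitance",
            "(input (cai from decaying-pool nope))\n (Membrane-capacitance")
        with pytest.raises(WiringError, match="nope"):
            _compile(src)

    def test_ambiguous_outputs_need_explicit_name(self):
        src = """(Membrane-potential amb
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (input (x from simulation-like s))
                  (Ohmic-current Leak (E = -65 mV) (g_max = 0.1)))"""
        # a two-output source: use the pore component with two outputs
        src = """(Membrane-potential amb
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (input (x from pore p2))
                  (Ohmic-current Leak (E = -65 mV) (g_max = 0.1)
                   (pore (name p2) (out gbar gleak)
                    (const gbar = 1) (const gleak = 2))))"""
        with pytest.raises((AmbiguityError, StructuralError)):
            _compile(src)

    def test_explicit_output_name_resolves(self):
        src = """(Membrane-potential two
                  (Membrane-capacitance 1.0 uF/cm*cm)
                  (input (camix from decaying-pool ca2 cac))
                  (Ohmic-current CaX
                   (gating m (power 1) (forward-rate 1) (reverse-rate 1))
                   (permeability (out pmax) (const pmax = 1e-5))
                   (permeating-ion (name ca) (valence 2)
                    (ci = camix) (const co = 2)))
                  (decaying-pool (name ca2) (out cac)
                   (current CaX)
                   (const B = 0.01) (const steady = 1e-4) (const tau = 1)))"""
        sys = _compile(src).sys
        wired = [e for n, k, e in sys.defs if n == "camix"]
        assert wired and wired[0] == Sym("ca2_cac")
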