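"""Code generation targets: solver module, Octave script, NMODL."""

import numpy as np
import pytest

from ioncomp import compile_model, fixtures
from ioncomp.expr import Neg, Sym
from ioncomp.odesystem import OdeSystem
from ioncomp.targets import (emit_nmodl, emit_octave_script,
                             emit_solver_function, read_nmodl_equations)

from conftest import HH_STATE_SUFFIX, hh_oracle_rhs


def _exec_module(src):
    ns = {}
    exec(compile(src, "<generated>", "exec"), ns)
    return ns


class TestSolverTarget:
    def test_hh_matches_hand_coded_oracle(self, hh_compiled):
        """Emitted right-hand side vs an independently hand-coded HH rhs at
        100 random state points, to relative 1e-9."""
        sys = hh_compiled.sys
        ns = _exec_module(emit_solver_function(sys))
        rng = np.random.default_rng(42)
        for _ in range(100):
            named = {"m": rng.uniform(0, 1), "h": rng.uniform(0, 1),
                     "n": rng.uniform(0, 1), "v": rng.uniform(-20, 120)}
            y = [0.0] * 4
            for k, flat in HH_STATE_SUFFIX.items():
                y[sys.state_index[flat]] = named[k]
            got = ns["rhs"](0.0, y)
            expected = hh_oracle_rhs(0.0, named)
            for k, flat in HH_STATE_SUFFIX.items():
                assert got[sys.state_index[flat]] == pytest.approx(
                    expected[k], rel=1e-9, abs=1e-12)

    def test_single_decay_equation(self):
        sys = OdeSystem(name="one", defs=[], relations=[],
                        odes=[("x", Neg(Sym("x")))], state_index={"x": 0})
        ns = _exec_module(emit_solver_function(sys))
        assert ns["rhs"](0.0, [3.0]) == [-3.0]

    def test_emission_deterministic(self, hh_compiled):
        a = emit_solver_function(hh_compiled.sys)
        b = emit_solver_function(hh_compiled.sys)
        assert a == b

    @pytest.mark.parametrize("n", [1, 3])
    def test_random_models_emit_loadable_code(self, n):
        for seed in range(40):
            sys = compile_model(fixtures.random_model(seed, n)).sys
            ns = _exec_module(emit_solver_function(sys))
            y0 = ns["initial_state"](-60.0)
            dy = ns["rhs"](0.0, y0)
            assert len(dy) == sys.n_states
            assert all(np.isfinite(v) for v in dy)

    def test_initial_state_matches_runtime(self, kr_compiled):
        from ioncomp.runtime import steady_state_init
        ns = _exec_module(emit_solver_function(kr_compiled.sys))
        got = np.array(ns["initial_state"](-80.0))
        want = steady_state_init(kr_compiled.sys, -80.0)
        assert got == pytest.approx(want, abs=1e-12)


RELATION_MODEL = """
(Membrane-potential rel
 (Membrane-capacitance 1.0 uF/cm*cm)
 (Ohmic-current Na
  (gating (out m)
   (fun minf (V) = 1 / (1 + exp(-(V + 40) / 6)))
   (fun mtau (V) = 0.2 + 1 / (1 + exp((V + 40) / 20)))
   (d (m) = ((minf V) - m) / (mtau V)))
  (pore (out gbar) (const gbar = 10))
  (permeating-ion (name na) (out e) (const e = 50))))
"""


class TestOctaveTarget:
    def test_one_function_per_relation(self):
        sys = compile_model(RELATION_MODEL).sys
        script = emit_octave_script(sys)
        assert len(sys.relations) == 2
        for rel in sys.relations:
            assert f"function out = {rel.name}(" in script

    def test_script_structure(self, hh_compiled):
        cfg = hh_compiled.simulations[0]
        script = emit_octave_script(hh_compiled.sys, cfg)
        assert "function dy = hh_rhs(t, y)" in script
        assert "function y0 = hh_init(v0)" in script
        assert "0.0:0.0001:2000;" in script

    def test_emission_deterministic(self, kr_compiled):
        assert (emit_octave_script(kr_compiled.sys)
                == emit_octave_script(kr_compiled.sys))


class TestNmodlTarget:
    def test_na_file_declares_useion(self, hh_compiled):
        files = dict(emit_nmodl(hh_compiled.sys, hh_compiled.info))
        assert "USEION na READ ena WRITE ina" in files["Na.mod"]

    def test_leak_uses_nonspecific_current(self, hh_compiled):
        files = dict(emit_nmodl(hh_compiled.sys, hh_compiled.info))
        assert "NONSPECIFIC_CURRENT" in files["Leak.mod"]

    def test_merged_single_suffix_three_currents(self, hh_compiled):
        ((_, text),) = emit_nmodl(hh_compiled.sys, hh_compiled.info, merge=True)
        assert text.count("SUFFIX") == 1
        for i_name in ("Na_i", "K_i", "Leak_i"):
            assert f"{i_name} = " in text

    def test_merged_has_no_duplicate_identifiers(self, kr_compiled):
        import re
        ((_, text),) = emit_nmodl(kr_compiled.sys, kr_compiled.info, merge=True)
        names = []
        block = None
        for line in text.splitlines():
            s = line.strip()
            if s.startswith(("PARAMETER", "STATE", "ASSIGNED")):
                block = s.split()[0]
                continue
            if s == "}":
                block = None
                continue
            if block and s:
                names.append(s.split()[0])
        assert len(names) == len(set(names))

    def test_merge_preserves_equations_up_to_renaming(self, hh_compiled):
        files = emit_nmodl(hh_compiled.sys, hh_compiled.info, merge=False)
        merged = emit_nmodl(hh_compiled.sys, hh_compiled.info, merge=True)
        unmerged_eqs = frozenset().union(
            *[read_nmodl_equations(t) for _, t in files])
        merged_eqs = read_nmodl_equations(merged[0][1])
        assert unmerged_eqs == merged_eqs

    def test_kinetic_scheme_emits_kinetic_block(self, kr_compiled):
        files = dict(emit_nmodl(kr_compiled.sys, kr_compiled.info))
        narsg = files["Narsg.mod"]
        assert "KINETIC" in narsg and "~ " in narsg
        assert "CONSERVE" in narsg
        assert "METHOD sparse" in narsg
        assert "STEADYSTATE sparse" in narsg

    def test_hh_gates_use_cnexp(self, hh_compiled):
        files = dict(emit_nmodl(hh_compiled.sys, hh_compiled.info))
        assert "SOLVE states METHOD cnexp" in files["Na.mod"]

    def test_pool_mechanism_reads_current_writes_concentration(self, kr_compiled):
        files = dict(emit_nmodl(kr_compiled.sys, kr_compiled.info))
        pool = files["ca_pool.mod"]
        assert "USEION ca READ ica WRITE cai" in pool

    def test_ghk_helper_emitted_once_for_ghk_models(self, kr_compiled):
        files = dict(emit_nmodl(kr_compiled.sys, kr_compiled.info))
        assert files["CaP.mod"].count("FUNCTION ghk(") == 1
        assert "FUNCTION ghk(" not in files["CaBK.mod"]
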