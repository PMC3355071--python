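"""Expressions, entities and environments."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ioncomp.entities import (ASSIGNMENT, PARAMETER, RATE, REACTION, RELATION,
                              Entity, Environment, build_entity, extend_env)
from ioncomp.errors import (EvaluationError, GrammarError, RedefinitionError)
from ioncomp.expr import (Apply, Binary, Neg, Num, Sym, eval_expr, free_vars,
                          parse_expr, subst)
from ioncomp.sexpr import parse_sexpr
from collections import ChainMap


ALPHA_M = "(2.5 - 0.1*V)/((exp (2.5 - 0.1*V)) - 1)"
BETA_M = "(0.125 * exp(-V/80))"


class TestParseEval:
    def test_alpha_m_at_zero(self):
        # independent evaluation of the printed rate expression
        expected = 2.5 / (math.exp(2.5) - 1.0)
        got = eval_expr(parse_expr(ALPHA_M), {"v": 0.0})
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.22356, rel=1e-4)

    def test_beta_m_at_zero(self):
        assert eval_expr(parse_expr(BETA_M), {"v": 0.0}) == pytest.approx(0.125)

    def test_both_application_styles(self):
        prefix = eval_expr(parse_expr("(exp x)"), {"x": 1.0})
        juxta = eval_expr(parse_expr("exp(x)"), {"x": 1.0})
        assert prefix == juxta == pytest.approx(math.e)

    def test_unbound_symbol_is_error(self):
        with pytest.raises(EvaluationError, match="x"):
            eval_expr(Sym("x"), {})

    def test_arity_mismatch_is_error(self):
        rel = Entity(name="f", kind=RELATION, formals=("a",), rhs=Sym("a"))
        with pytest.raises(EvaluationError, match="argument"):
            eval_expr(Apply("f", (Num(1.0), Num(2.0))), {}, {"f": rel})

    def test_division_by_zero_propagates_inf(self):
        assert eval_expr(parse_expr("1 / x"), {"x": 0.0}) == math.inf
        assert math.isnan(eval_expr(parse_expr("x / x"), {"x": 0.0}))

    def test_exp_overflow_propagates_inf(self):
        assert eval_expr(parse_expr("exp(x)"), {"x": 1e4}) == math.inf

    def test_power_right_associative(self):
        assert eval_expr(parse_expr("2 ^ 3 ^ 2"), {}) == 512.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_eval_matches_recursive_oracle(self, seed):
        """Tree-walk evaluation agrees with a direct recursive oracle."""
        import random
        rng = random.Random(seed)

        def rand_expr(depth):
            if depth == 0 or rng.random() < 0.3:
                if rng.random() < 0.5:
                    return ("num", rng.uniform(-3, 3))
                return ("sym", rng.choice("xyz"))
            kind = rng.choice(["+", "-", "*", "/", "neg", "exp"])
            if kind == "neg":
                return ("neg", rand_expr(depth - 1))
            if kind == "exp":
                return ("exp", rand_expr(depth - 1))
            return (kind, rand_expr(depth - 1), rand_expr(depth - 1))

        def to_expr(n):
            if n[0] == "num":
                return Num(n[1])
            if n[0] == "sym":
                return Sym(n[1])
            if n[0] == "neg":
                return Neg(to_expr(n[1]))
            if n[0] == "exp":
                return Apply("exp", (to_expr(n[1]),))
            return Binary(n[0], to_expr(n[1]), to_expr(n[2]))

        def oracle(n, env):
            if n[0] == "num":
                return n[1]
            if n[0] == "sym":
                return env[n[1]]
            if n[0] == "neg":
                return -oracle(n[1], env)
            if n[0] == "exp":
                try:
                    return math.exp(oracle(n[1], env))
                except OverflowError:
                    return math.inf
            a, b = oracle(n[1], env), oracle(n[2], env)
            if n[0] == "+":
                return a + b
            if n[0] == "-":
                return a - b
            if n[0] == "*":
                return a * b
            try:
                return a / b
            except ZeroDivisionError:
                return math.nan if a == 0 else math.copysign(math.inf, a) * math.copysign(1, b)

        tree = rand_expr(4)
        env = {s: rng.uniform(-2, 2) for s in "xyz"}
        expected = oracle(tree, env)
        got = eval_expr(to_expr(tree), env)
        if math.isnan(expected):
            assert math.isnan(got)
        elif math.isinf(expected):
            assert got == expected
        else:
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)


class TestFreeVars:
    def test_number_has_none(self):
        assert free_vars(Num(2000.0)) == frozenset()

    def test_printed_rate_expression(self):
        assert free_vars(parse_expr(ALPHA_M)) == {"v"}

    def test_conductance_product(self):
        assert free_vars(parse_expr("g_max * m*m*m * h")) == {"g_max", "m", "h"}

    def test_applied_relation_names_are_dependencies(self):
        assert free_vars(parse_expr("(alpha V) * (1 - m)")) == {"alpha", "m", "v"}


class TestSubst:
    def test_basic(self):
        e = parse_expr("x + y")
        assert subst(e, {"x": Sym("a")}) == parse_expr("a + y")

    def test_empty_is_identity(self):
        e = parse_expr("x * exp(y)")
        assert subst(e, {}) == e

    def test_nested_chain_inner_wins(self):
        chain = ChainMap({"x": Num(1.0)}, {"x": Num(9.0), "y": Num(2.0)})
        assert subst(parse_expr("x * y"), chain) == Binary("*", Num(1.0), Num(2.0))

    def test_absent_identifier_passes_through(self):
        assert subst(Sym("q"), {"x": Num(1.0)}) == Sym("q")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sampled_from(["x + y", "exp(x) * z", "x / (y - z)", "x ^ y"]))
    def test_substituted_names_no_longer_free(self, text):
        e = parse_expr(text)
        s = {"x": Num(1.0), "y": Sym("w")}
        assert not (free_vars(subst(e, s)) & set(s))


class TestEntities:
    def test_const_becomes_parameter(self):
        ent = build_entity(parse_sexpr("(const duration = 2000)"))
        assert ent.kind == PARAMETER and ent.name == "duration"
        assert eval_expr(ent.rhs, {}) == 2000.0

    def test_rate_declaration(self):
        ent = build_entity(parse_sexpr("(d (m) = alpha(V)*(1 - m) - beta(V)*m)"))
        assert ent.kind == RATE and ent.state == "m"
        assert free_vars(ent.rhs) == {"alpha", "beta", "m", "v"}

    def test_relation_declaration(self):
        ent = build_entity(parse_sexpr("(fun f (a b) = a + b)"))
        assert ent.kind == RELATION and ent.formals == ("a", "b")

    def test_assignment(self):
        ent = build_entity(parse_sexpr("(g = gbar * m)"))
        assert ent.kind == ASSIGNMENT

    def test_minimal_reversible_reaction(self):
        ent = build_entity(parse_sexpr(
            "(reaction r (transitions (<-> C O 2 1)) (open O))"))
        assert ent.kind == REACTION
        assert ent.states == ("C", "O")
        assert len(ent.transitions) == 1 and ent.conserve == 1.0

    def test_const_with_free_symbol_rejected(self):
        with pytest.raises(GrammarError):
            build_entity(parse_sexpr("(const x = y + 1)"))

    def test_unknown_head_rejected(self):
        with pytest.raises(GrammarError):
            build_entity(parse_sexpr("(frobnicate x 1)"))

    def test_reaction_undeclared_state_rejected(self):
        with pytest.raises(GrammarError, match="undeclared"):
            build_entity(parse_sexpr(
                "(reaction r (states A B) (transitions (<-> A C 1 1)))"))

    def test_reaction_disconnected_graph_rejected(self):
        with pytest.raises(GrammarError, match="connected"):
            build_entity(parse_sexpr(
                "(reaction r (states A B C D) "
                "(transitions (<-> A B 1 1) (<-> C D 1 1)))"))


class TestEnvironment:
    def test_extend_twice_distinct(self):
        env = Environment()
        e1 = extend_env(env, Entity(name="a", kind=PARAMETER, rhs=Num(1.0)))
        e2 = extend_env(e1, Entity(name="b", kind=PARAMETER, rhs=Num(2.0)))
        assert "a" in e2 and "b" in e2

    def test_extend_duplicate_is_error(self):
        env = extend_env(Environment(), Entity(name="a", kind=PARAMETER, rhs=Num(1.0)))
        with pytest.raises(RedefinitionError):
            extend_env(env, Entity(name="a", kind=PARAMETER, rhs=Num(2.0)))

    def test_extension_is_persistent(self):
        env = extend_env(Environment(), Entity(name="a", kind=PARAMETER, rhs=Num(1.0)))
        env2 = extend_env(env, Entity(name="b", kind=PARAMETER, rhs=Num(2.0)))
        assert "b" not in env and "b" in env2

    def test_lookup_matches_assoc_list_oracle(self):
        """100 random extensions agree with an association-list oracle."""
        import random
        rng = random.Random(7)
        env = Environment()
        assoc = []
        for k in range(100):
            name = f"n{rng.randrange(200)}"
            if any(n == name for n, _ in assoc):
                with pytest.raises(RedefinitionError):
                    extend_env(env, Entity(name=name, kind=PARAMETER, rhs=Num(k)))
                continue
            env = extend_env(env, Entity(name=name, kind=PARAMETER, rhs=Num(k)))
            assoc.append((name, float(k)))
        for name, value in assoc:
            assert env.lookup(name).rhs == Num(value)
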