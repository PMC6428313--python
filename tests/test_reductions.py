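"""Hardness-construction generators against their brute-force oracles.

The correctness theorem of every construction is an "if and only if":
the classical instance is a yes-instance exactly when the built DBU
instance model-checks true.  These tests enforce that equivalence on
exhaustive or densely sampled small domains, plus the structural claims
the constructions make about their output models.
"""

import itertools
import random
from math import comb

import pytest

from dbu.formulas import Atom, Not, conjoin, disjoin
from dbu.models import check_relation_class, equivalence_groups
from dbu.reductions import (CNFInstance, ColoredGraph, QBFInstance,
                            WSatInstance, oracle_mcc, oracle_qbf, oracle_sat,
                            oracle_wsat, reduce_mcc, reduce_sat, reduce_tqbf,
                            reduce_wsat)
from dbu.semantics import apply_sequence
from dbu.solver import parameters, solve


def random_cnf(rng, n_vars, n_clauses, width):
    clauses = []
    for _ in range(n_clauses):
        k = rng.randint(1, min(width, n_vars))
        vs = rng.sample(range(1, n_vars + 1), k)
        clauses.append(tuple(v if rng.random() < 0.5 else -v for v in vs))
    return CNFInstance(n_vars, clauses, max_width=width)


def cnf_matrix(cnf):
    return conjoin([
        disjoin([Atom(f"x{l}") if l > 0 else Not(Atom(f"x{-l}"))
                 for l in clause])
        for clause in cnf.clauses])


def random_colored_graph(rng, max_vertices, k):
    n = rng.randint(k, max_vertices)
    vertices = [f"v{i}" for i in range(n)]
    coloring = {v: (i % k) + 1 for i, v in enumerate(vertices)}  # all colors used
    edges = [e for e in itertools.combinations(vertices, 2)
             if rng.random() < 0.5]
    return ColoredGraph(vertices, edges, coloring)


class TestOracles:
    def test_qbf_basics(self):
        x = Atom("x")
        assert oracle_qbf(QBFInstance([("exists", "x")], x)) is True
        assert oracle_qbf(QBFInstance([("forall", "x")], x)) is False
        phi = Atom("x1") | Atom("x2")
        assert oracle_qbf(QBFInstance(
            [("forall", "x1"), ("exists", "x2")], phi)) is True
        assert oracle_qbf(QBFInstance(
            [("forall", "x1"), ("forall", "x2")], phi)) is False

    def test_sat_basics(self):
        assert oracle_sat(CNFInstance(1, [(1, -1)])) is True
        assert oracle_sat(CNFInstance(1, [(1,), (-1,)])) is False
        assert oracle_sat(CNFInstance(2, [])) is True

    def test_mcc_basics(self):
        k22 = ColoredGraph(
            ["a1", "a2", "b1", "b2"],
            [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")],
            {"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        assert oracle_mcc(k22, 2) is True
        isolated = ColoredGraph(["u", "v"], [], {"u": 1, "v": 2})
        assert oracle_mcc(isolated, 2) is False
        assert oracle_mcc(ColoredGraph(["u"], [], {"u": 1}), 1) is True

    def test_wsat_basics(self):
        assert oracle_wsat(WSatInstance(CNFInstance(2, [(-1, -2)], 2), 2)) is False
        assert oracle_wsat(WSatInstance(CNFInstance(2, [(1, 2)], 2), 1)) is True
        assert oracle_wsat(WSatInstance(CNFInstance(3, [], 2), 2)) is True


class TestQuantifierConstruction:
    def test_worked_example_and_final_model_structure(self):
        phi = Atom("x1") | Atom("x2")
        inst = reduce_tqbf(QBFInstance(
            [("exists", "x1"), ("forall", "x2")], phi))
        assert solve(inst) is True
        final = apply_sequence(inst.state, inst.actions).model

        # four groups of worlds over the y-false region, sizes 3/2/2/1
        y_false = [w for w in final.worlds if "y" not in final.valuation[w]]
        groups = equivalence_groups(final.restrict(y_false), "a")
        assert len(groups) == 4
        assert sorted(len(g) for g in groups) == [1, 2, 2, 3]

        # every variable-agent equivalence class has at most (and some
        # exactly) two members
        for agent in ("1", "2"):
            sizes = [len(c) for c in equivalence_groups(final, agent)]
            assert max(sizes) == 2

    def test_final_model_independent_of_matrix(self):
        def final_fingerprint(matrix):
            inst = reduce_tqbf(QBFInstance(
                [("forall", "x1"), ("forall", "x2")], matrix))
            m = apply_sequence(inst.state, inst.actions).model
            return (m.worlds, dict(m.relations), dict(m.valuation))

        a = final_fingerprint(Atom("x1") | Atom("x2"))
        b = final_fingerprint(Atom("x1") & ~Atom("x2"))
        assert a == b

    def test_all_models_are_s5(self):
        inst = reduce_tqbf(QBFInstance(
            [("exists", "x1"), ("forall", "x2")], Atom("x1")))
        assert check_relation_class(inst.state.model, "S5")
        for action in inst.actions:
            assert check_relation_class(action.model, "S5")

    def test_initial_group_is_one_class_of_agent_a(self):
        inst = reduce_tqbf(QBFInstance(
            [("exists", "x1"), ("exists", "x2"), ("exists", "x3")], Atom("x1")))
        m = inst.state.model
        groups = equivalence_groups(m, "a")
        assert frozenset({"w0", "w1", "w2", "w3"}) in groups

    @pytest.mark.parametrize("pattern",
                             list(itertools.product(["forall", "exists"],
                                                    repeat=3)))
    def test_equivalence_with_oracle_m3(self, pattern):
        seed = sum((q == "exists") << i for i, q in enumerate(pattern))
        rng = random.Random(seed)
        vars_ = ["x1", "x2", "x3"]
        for _ in range(20):
            matrix = cnf_matrix(random_cnf(rng, 3, rng.randint(1, 2), 3))
            q = QBFInstance(list(zip(pattern, vars_)), matrix)
            assert solve(reduce_tqbf(q)) == oracle_qbf(q), q

    def test_rejects_empty_prefix(self):
        with pytest.raises(ValueError):
            reduce_tqbf(QBFInstance([], conjoin([])))


class TestSatConstruction:
    def test_tautological_clause(self):
        assert solve(reduce_sat(CNFInstance(1, [(1, -1)]))) is True

    def test_contradiction(self):
        assert solve(reduce_sat(CNFInstance(1, [(1,), (-1,)]))) is False

    @pytest.mark.parametrize("seed", range(8))
    def test_equivalence_with_brute_force(self, seed):
        rng = random.Random(seed)
        for _ in range(25):
            c = random_cnf(rng, rng.randint(1, 3), rng.randint(0, 4), 3)
            assert solve(reduce_sat(c)) == oracle_sat(c), c

    def test_parameters_constant_across_inputs(self):
        rng = random.Random(0)
        vectors = set()
        for _ in range(10):
            c = random_cnf(rng, rng.randint(2, 3), rng.randint(2, 4), 3)
            pv = parameters(reduce_sat(c))
            vectors.add((pv.a, pv.e, pv.f, pv.o))
            # bounded by the fixed clause width: the largest precondition is
            # ~D[a](z & [c]) with a fully negated 3-literal clause, size 20
            assert pv.c <= 20
            assert pv.u == c.num_vars + len(c.clauses)
        assert vectors == {(1, 2, 1, 0)}

    def test_rejects_wide_clauses(self):
        with pytest.raises(ValueError):
            CNFInstance(4, [(1, 2, 3, 4)])


class TestCliqueConstruction:
    def test_triangle_with_three_colors(self):
        g = ColoredGraph(["u", "v", "w"],
                         [("u", "v"), ("v", "w"), ("u", "w")],
                         {"u": 1, "v": 2, "w": 3})
        assert solve(reduce_mcc(g, 3)) is True

    def test_path_misses_one_edge(self):
        g = ColoredGraph(["u", "v", "w"], [("u", "v"), ("v", "w")],
                         {"u": 1, "v": 2, "w": 3})
        assert solve(reduce_mcc(g, 3)) is False

    def test_single_edge_two_colors(self):
        g = ColoredGraph(["u", "v"], [("u", "v")], {"u": 1, "v": 2})
        inst = reduce_mcc(g, 2)
        assert solve(inst) is True
        assert parameters(inst).f == 1  # goal is the single atom r:1:2

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_parameter_pinning(self, k):
        rng = random.Random(k)
        for _ in range(3):
            g = random_colored_graph(rng, 2 * k, k)
            pv = parameters(reduce_mcc(g, k))
            assert pv.f == 2 * comb(k, 2) - 1
            assert pv.u == k + comb(k, 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_equivalence_with_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(8):
            k = rng.randint(1, 3)
            g = random_colored_graph(rng, 6, k)
            assert solve(reduce_mcc(g, k)) == oracle_mcc(g, k), (g, k)

    def test_rejects_bad_coloring(self):
        g = ColoredGraph(["u", "v"], [], {"u": 1, "v": 5})
        with pytest.raises(ValueError):
            reduce_mcc(g, 2)


class TestWeightedSatConstruction:
    def test_one_of_two_variables(self):
        w = WSatInstance(CNFInstance(2, [(1, 2)], 2), 1)
        assert solve(reduce_wsat(w)) is True

    def test_two_positive_units_need_weight_two(self):
        w = WSatInstance(CNFInstance(2, [(1,), (2,)], 2), 1)
        assert solve(reduce_wsat(w)) is False

    def test_weight_zero_fails_positive_unit(self):
        w = WSatInstance(CNFInstance(2, [(1,)], 2), 0)
        assert solve(reduce_wsat(w)) is False

    def test_update_count_equals_weight(self):
        for k in range(0, 4):
            w = WSatInstance(CNFInstance(4, [(1, -2)], 2), k)
            assert parameters(reduce_wsat(w)).u == k

    def test_exhaustive_small_domain(self):
        # all k for several 2CNFs with up to 4 variables
        rng = random.Random(11)
        for _ in range(12):
            m = rng.randint(2, 4)
            cnf = random_cnf(rng, m, rng.randint(0, 4), 2)
            for k in range(0, m + 1):
                w = WSatInstance(cnf, k)
                assert solve(reduce_wsat(w)) == oracle_wsat(w), (cnf, k)

    def test_rejects_overweight(self):
        with pytest.raises(ValueError):
            WSatInstance(CNFInstance(2, [], 2), 3)


class TestOutputsAreWellBehavedModels:
    """All constructions advertise S5 relations (the false-belief fixture
    is the only intentionally non-S5 model in the package)."""

    def build_all(self):
        rng = random.Random(5)
        yield reduce_tqbf(QBFInstance([("forall", "x1"), ("exists", "x2")],
                                      Atom("x1") | Atom("x2")))
        yield reduce_sat(random_cnf(rng, 3, 3, 3))
        yield reduce_mcc(random_colored_graph(rng, 5, 2), 2)
        yield reduce_wsat(WSatInstance(random_cnf(rng, 3, 2, 2), 2))

    def test_s5_and_size_bound(self):
        for inst in self.build_all():
            assert check_relation_class(inst.state.model, "S5")
            for action in inst.actions:
                assert check_relation_class(action.model, "S5")
            final = apply_sequence(inst.state, inst.actions)
            e = max((len(a.model.events) for a in inst.actions), default=0)
            bound = len(inst.state.model.worlds) * max(e, 1) ** len(inst.actions)
            assert len(final.model.worlds) <= bound
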