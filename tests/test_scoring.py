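import itertools
import math

import numpy as np
import pytest

from conftest import make_bn, make_dataset
from oracles import cpdag_class, enumerate_dags, naive_bde, naive_family_score

from methylbn.exceptions import CycleError
from methylbn.preprocess import binarize_counts
from methylbn.scoring import (
    ADD,
    DELETE,
    REVERSE,
    BDeCache,
    Dag,
    bde_score,
    delta_score,
    family_score,
)
from methylbn.synthetic import sample_counts


def random_dataset(rng, n, k):
    return make_dataset(rng.integers(0, 2, size=(n, k)))


class TestDag:
    def test_cycle_prevented_on_add(self):
        g = Dag("ABC", [("A", "B"), ("B", "C")])
        with pytest.raises(CycleError):
            g.add_arc("C", "A")
        assert g.arcs == {("A", "B"), ("B", "C")}

    def test_cycle_prevented_on_reverse(self):
        g = Dag("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        with pytest.raises(CycleError):
            g.reverse_arc("A", "C")

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            Dag("AB", [("A", "A")])

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError):
            Dag("AB", [("A", "Z")])

    def test_reverse_and_remove(self):
        g = Dag("AB", [("A", "B")])
        g.reverse_arc("A", "B")
        assert g.arcs == {("B", "A")}
        g.remove_arc("B", "A")
        assert g.arcs == set()

    def test_topological_order(self):
        g = Dag("ABCD", [("A", "B"), ("B", "C"), ("A", "D")])
        order = g.topological_order()
        pos = {v: i for i, v in enumerate(order)}
        for u, v in g.arcs:
            assert pos[u] < pos[v]

    def test_descendant_map(self):
        g = Dag("ABC", [("A", "B"), ("B", "C")])
        assert g.descendant_map() == {"A": {"B", "C"}, "B": {"C"}, "C": set()}

    def test_copy_is_independent(self):
        g = Dag("AB", [("A", "B")])
        h = g.copy()
        h.remove_arc("A", "B")
        assert g.has_arc("A", "B") and not h.has_arc("A", "B")


class TestFamilyScore:
    def test_beta_binomial_closed_form(self):
        # one 0 and one 1, ess=1: marginal likelihood is exactly 1/8
        d = make_dataset([[0, 0], [1, 1]], variables=["X", "Treatment"])
        s = family_score(d, "X", [], ess=1.0)
        assert s == pytest.approx(math.log(1 / 8), abs=1e-10)

    def test_zero_samples_scores_zero(self):
        d = make_dataset(np.zeros((0, 2), dtype=int), variables=["X", "Treatment"])
        assert family_score(d, "X", []) == 0.0
        assert family_score(d, "X", ["Treatment"]) == 0.0

    def test_matches_naive_oracle(self, rng):
        d = random_dataset(rng, 25, 4)
        rows = [tuple(r) for r in d.values]
        for child in range(4):
            others = [i for i in range(4) if i != child]
            for k in range(3):
                for parents in itertools.combinations(others, k):
                    got = family_score(
                        d, d.variables[child], [d.variables[p] for p in parents], ess=1.0
                    )
                    want = naive_family_score(rows, child, list(parents), ess=1.0)
                    assert got == pytest.approx(want, abs=1e-9)

    def test_invalid_ess(self):
        d = make_dataset([[0, 1]], variables=["X", "Treatment"])
        with pytest.raises(ValueError):
            family_score(d, "X", [], ess=0.0)

    def test_child_in_parents_rejected(self):
        d = make_dataset([[0, 1]], variables=["X", "Treatment"])
        with pytest.raises(ValueError):
            family_score(d, "X", ["X"])

    def test_unknown_variable_rejected(self):
        d = make_dataset([[0, 1]], variables=["X", "Treatment"])
        with pytest.raises(ValueError):
            family_score(d, "X", ["Nope"])


class TestBdeScore:
    def test_empty_graph_is_sum_of_parentless_families(self, rng):
        d = random_dataset(rng, 20, 3)
        g = Dag(d.variables)
        total = sum(family_score(d, v, []) for v in d.variables)
        assert bde_score(d, g) == pytest.approx(total, abs=1e-12)

    def test_likelihood_equivalence_two_nodes(self, rng):
        d = random_dataset(rng, 30, 2)
        a, b = d.variables
        s1 = bde_score(d, Dag(d.variables, [(a, b)]))
        s2 = bde_score(d, Dag(d.variables, [(b, a)]))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_three_node_dag_matches_naive_oracle(self, rng):
        d = random_dataset(rng, 20, 3)
        rows = [tuple(r) for r in d.values]
        arcs = [(d.variables[0], d.variables[2]), (d.variables[1], d.variables[2])]
        got = bde_score(d, Dag(d.variables, arcs))
        assert got == pytest.approx(naive_bde(rows, d.variables, arcs), abs=1e-9)

    def test_node_mismatch_rejected(self, rng):
        d = random_dataset(rng, 10, 3)
        with pytest.raises(ValueError):
            bde_score(d, Dag(["A", "B"]))

    def test_score_equivalence_classes_three_nodes(self, rng):
        d = random_dataset(rng, 30, 3)
        nodes = list(d.variables)
        classes = {}
        for arcs in enumerate_dags(nodes):
            key = cpdag_class(nodes, arcs)
            classes.setdefault(key, []).append(bde_score(d, Dag(nodes, arcs)))
        assert sum(len(v) for v in classes.values()) == 25
        for scores in classes.values():
            assert max(scores) - min(scores) < 1e-9

    def test_decomposability(self, rng):
        d = random_dataset(rng, 25, 4)
        v = list(d.variables)
        g1 = Dag(v, [(v[0], v[1])])
        g2 = Dag(v, [(v[0], v[1]), (v[2], v[3])])
        # only v[3]'s family differs between g1 and g2
        diff = bde_score(d, g2) - bde_score(d, g1)
        fam_diff = family_score(d, v[3], [v[2]]) - family_score(d, v[3], [])
        assert diff == pytest.approx(fam_diff, abs=1e-12)

    def test_monotone_data_support(self):
        bn = make_bn([("A", "B")], {"A": [0.5], "B": [0.1, 0.9], "Treatment": [0.5]})
        d = binarize_counts(sample_counts(bn, 1000, seed=4))
        dep = Dag(d.variables, [("A", "B")])
        empty = Dag(d.variables)
        assert bde_score(d, dep) > bde_score(d, empty)


class TestDeltaScore:
    def test_add_then_delete_cancels(self, rng):
        d = random_dataset(rng, 20, 3)
        g = Dag(d.variables)
        a, b = d.variables[0], d.variables[1]
        d1 = delta_score(d, g, (ADD, a, b))
        g.add_arc(a, b)
        d2 = delta_score(d, g, (DELETE, a, b))
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_delta_equals_full_rescore(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dataset(rng, 30, 4)
        v = list(d.variables)
        g = Dag(v, [(v[0], v[1]), (v[1], v[2])])
        moves = [(ADD, v[0], v[3]), (DELETE, v[0], v[1]), (REVERSE, v[1], v[2])]
        for move in moves:
            delta = delta_score(d, g, move)
            h = g.copy()
            op, u, w = move
            {ADD: h.add_arc, DELETE: h.remove_arc, REVERSE: h.reverse_arc}[op](u, w)
            assert delta == pytest.approx(bde_score(d, h) - bde_score(d, g), abs=1e-9)

    def test_reverse_decomposes_into_delete_plus_add(self, rng):
        d = random_dataset(rng, 20, 3)
        v = list(d.variables)
        g = Dag(v, [(v[0], v[1])])
        rev = delta_score(d, g, (REVERSE, v[0], v[1]))
        dele = delta_score(d, g, (DELETE, v[0], v[1]))
        h = g.copy()
        h.remove_arc(v[0], v[1])
        add = delta_score(d, h, (ADD, v[1], v[0]))
        assert rev == pytest.approx(dele + add, abs=1e-12)

    def test_illegal_moves_signal_none(self, rng):
        d = random_dataset(rng, 10, 3)
        v = list(d.variables)
        g = Dag(v, [(v[0], v[1]), (v[1], v[2])])
        assert delta_score(d, g, (ADD, v[0], v[1])) is None  # already present
        assert delta_score(d, g, (ADD, v[2], v[0])) is None  # cycle
        assert delta_score(d, g, (DELETE, v[2], v[0])) is None  # absent
        assert delta_score(d, g, (ADD, v[0], v[0])) is None  # self-loop

    def test_cache_reuse_consistent(self, rng):
        d = random_dataset(rng, 30, 4)
        cache = BDeCache(d, ess=1.0)
        g = Dag(d.variables)
        a, b = d.variables[:2]
        with_cache = delta_score(d, g, (ADD, a, b), cache=cache)
        without = delta_score(d, g, (ADD, a, b))
        assert with_cache == pytest.approx(without, abs=1e-12)
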