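import itertools

import numpy as np
import pytest

from mitocompare.gene_order import (GeneOrder, apply_op, breakpoint_distance,
                                    canonical_order, minimal_scenario,
                                    read_order, write_order)
from mitocompare.simulate import SimConfig, simulate_pair
from tests.conftest import build_genome


def order(labels):
    """'a b -c' -> GeneOrder with signed elements."""
    elems = [(t[1:], "-") if t.startswith("-") else (t, "+")
             for t in labels.split()]
    return GeneOrder(elements=elems)


# --- independent oracle: plain nested enumeration of op sequences ----------

def _oracle_ops(elems):
    n = len(elems)
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 == n:
                continue
            for k in range(n - (j - i + 1) + 1):
                if k != i:
                    yield {"op": "relocate", "block": [i, j], "dest": k}
    for i in range(n):
        for j in range(i + 1, n):
            yield {"op": "swap", "i": i, "j": j}


def _oracle_apply(elems, op):
    lst = list(elems)
    if op["op"] == "relocate":
        i, j = op["block"]
        block, rest = lst[i:j + 1], lst[:i] + lst[j + 1:]
        k = op["dest"]
        return tuple(rest[:k] + block + rest[k:])
    i, j = op["i"], op["j"]
    lst[i], lst[j] = lst[j], lst[i]
    return tuple(lst)


def _oracle_equal(x, y):
    """Circular equality up to rotation and reflection-with-strand-flip."""
    def variants(t):
        flip = tuple((lab, "+" if s == "-" else "-") for lab, s in reversed(t))
        for base in (t, flip):
            for r in range(len(base)):
                yield base[r:] + base[:r]
    return any(v == tuple(y) for v in variants(tuple(x)))


def oracle_min_ops(a, b, max_depth):
    """Exhaustive breadth enumeration without pruning or dedup."""
    start, target = tuple(a.elements), tuple(b.elements)
    frontier = [start]
    if _oracle_equal(start, target):
        return 0
    for depth in range(1, max_depth + 1):
        nxt = []
        for state in frontier:
            for op in _oracle_ops(state):
                s2 = _oracle_apply(state, op)
                if _oracle_equal(s2, target):
                    return depth
                nxt.append(s2)
        frontier = nxt
    return None


# ---------------------------------------------------------------------------

class TestCanonicalOrder:
    CASSETTES = [
        ("cox1", "CDS", "+", "ATG" + "AAACCC" * 20 + "TAA"),
        ("trnA", "tRNA", "+", "ACGTAC" * 11),
        ("cox2", "CDS", "-", "ATG" + "AATCGC" * 15 + "TAA"),
        ("trnB", "tRNA", "+", "TTTTTT" * 10),
        ("rrnS", "rRNA", "+", "ACACAC" * 30),
    ]

    def test_rotation_invariance(self):
        g1 = build_genome(self.CASSETTES)
        g2 = build_genome(self.CASSETTES, rotate=142 + 66 + 16)  # at cox2 start
        assert canonical_order(g1).elements == canonical_order(g2).elements

    def test_reverse_complement_invariance(self):
        g1 = build_genome(self.CASSETTES)
        g2 = build_genome(self.CASSETTES, revcomp=True)
        assert canonical_order(g1).elements == canonical_order(g2).elements

    def test_anchor_first_on_plus_strand(self):
        g = build_genome(self.CASSETTES)
        o = canonical_order(g, anchor="cox2")
        assert o.elements[0] == ("cox2", "+")

    def test_restriction_to_trnas(self, sim_pair):
        f, _, _ = sim_pair
        trnas = {x.name for x in f.features if x.kind == "tRNA"}
        o = canonical_order(f, anchor="trnA", restrict_to=trnas)
        assert len(o.elements) == 22

    def test_missing_anchor_raises(self):
        g = build_genome(self.CASSETTES)
        with pytest.raises(KeyError):
            canonical_order(g, anchor="nope")


class TestBreakpointDistance:
    def test_identical_orders_zero(self):
        a = order("a b c d e")
        assert breakpoint_distance(a, a) == 0

    def test_three_gene_block_relocation_costs_three(self):
        a = order("g1 g2 g3 g4 g5 g6 g7 g8 g9 g10")
        b = order("g1 g5 g6 g7 g2 g3 g4 g8 g9 g10")  # block g2..g4 moved
        assert breakpoint_distance(a, b) == 3
        assert breakpoint_distance(b, a) == 3

    def test_full_reversal_with_strand_flip_is_identity(self):
        a = order("a b c d e")
        b = order("-e -d -c -b -a")
        assert breakpoint_distance(a, b) == 0

    def test_non_shared_labels_dropped(self):
        a = order("a b c x y")
        b = order("a b c z")
        assert breakpoint_distance(a, b) == 0

    def test_strand_flip_of_one_element_breaks_adjacencies(self):
        a = order("a b c d e")
        b = order("a -b c d e")
        assert breakpoint_distance(a, b) == 2


class TestMinimalScenario:
    def test_equal_orders_need_no_ops(self):
        a = order("a b c d e f")
        sc = minimal_scenario(a, a)
        assert sc.achieved and sc.op_count == 0

    def test_single_block_relocation_recovered(self):
        a = order("a b c d e f g h")
        planted = {"op": "relocate", "block": [1, 3], "dest": 4}
        b = GeneOrder(elements=list(apply_op(tuple(a.elements), planted)))
        sc = minimal_scenario(a, b, max_ops=3)
        assert sc.achieved and sc.op_count == 1
        assert oracle_min_ops(a, b, 1) == 1

    def test_replaying_ops_reaches_target(self):
        rng = np.random.default_rng(5)
        labels = [f"g{i}" for i in range(9)]
        a = GeneOrder(elements=[(l, "+") for l in labels])
        state = tuple(a.elements)
        for op in [{"op": "relocate", "block": [2, 4], "dest": 0},
                   {"op": "swap", "i": 6, "j": 8}]:
            state = apply_op(state, op)
        b = GeneOrder(elements=list(state))
        sc = minimal_scenario(a, b, max_ops=3)
        assert sc.achieved
        replay = tuple(sc.source)
        for op in sc.ops:
            replay = apply_op(replay, op)
        assert _oracle_equal(replay, sc.target)

    @pytest.mark.parametrize("seed,n,depth", [(0, 6, 1), (1, 6, 2), (2, 7, 2),
                                              (3, 8, 2)])
    def test_matches_exhaustive_enumeration(self, seed, n, depth):
        rng = np.random.default_rng(seed)
        a = GeneOrder(elements=[(f"g{i}", "+") for i in range(n)])
        state = tuple(a.elements)
        ops = list(_oracle_ops(state))
        for _ in range(depth):
            state = _oracle_apply(state, ops[int(rng.integers(len(ops)))])
        b = GeneOrder(elements=list(state))
        want = oracle_min_ops(a, b, depth)
        sc = minimal_scenario(a, b, max_ops=depth)
        assert sc.achieved and sc.op_count == want

    def test_depth_bound_reported_as_not_achieved(self):
        a = order("a b c d e f g h i j")
        b = order("b a d c f e h g j i")  # five disjoint swaps
        sc = minimal_scenario(a, b, max_ops=2)
        assert not sc.achieved and sc.ops == []

    def test_simulated_pair_scenario_matches_planted_moves(self):
        for n_moves in (1, 2):
            f, m, truth = simulate_pair(SimConfig(seed=4, n_moves=n_moves))
            sc = minimal_scenario(canonical_order(f), canonical_order(m),
                                  max_ops=3)
            assert sc.achieved and sc.op_count == n_moves
            assert len(truth.order_ops) == n_moves


class TestOrderFiles:
    def test_round_trip(self, tmp_path):
        o = order("cox1 -trnQ rrnS trnA")
        p = tmp_path / "order.txt"
        write_order(o, p)
        assert read_order(p).elements == o.elements
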