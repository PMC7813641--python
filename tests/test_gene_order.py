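import random

import pytest

from mitoarchitect.gene_order import (GeneOrder, breakpoint_distance,
                                      cyclic_signed_equal, map_events_on_tree,
                                      merge_sections, section_order)

from oracles import brute_force_breakpoints, circular_adjacencies


def partition_of(sections):
    return sorted(tuple(sorted(s.labels)) for s in sections)


def random_signed_order(rng, n, gid="g"):
    labels = [f"u{i}" for i in range(n)]
    rng.shuffle(labels)
    return GeneOrder(gid, [(u, rng.choice([1, -1])) for u in labels])


class TestMergeSections:
    def test_identical_circles_collapse(self):
        o1 = GeneOrder("g1", [("a", 1), ("b", 1), ("c", 1)])
        o2 = GeneOrder("g2", [("a", 1), ("b", 1), ("c", 1)])
        secs = merge_sections([o1, o2])
        assert len(secs) == 1
        assert secs[0].labels == ("a", "b", "c")
        assert secs[0].broken_cycle

    def test_orientation_flip_isolates_unit(self):
        """Flipping b breaks both its links while c-d and d-a persist."""
        o1 = GeneOrder("g1", [("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        o2 = GeneOrder("g2", [("a", 1), ("b", -1), ("c", 1), ("d", 1)])
        secs = merge_sections([o1, o2])
        assert partition_of(secs) == [("a", "c", "d"), ("b",)]

    def test_signed_reversal_equivalence(self):
        """-b,-a in one genome conserves the +a,+b adjacency of another."""
        o1 = GeneOrder("g1", [("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        o2 = GeneOrder("g2", [("b", -1), ("a", -1), ("c", 1), ("d", 1)])
        secs = merge_sections([o1, o2])
        # a-b link survives; a|c and b|c etc. adjacencies differ
        assert ("a", "b") in partition_of(secs)

    def test_singleton_for_private_unit(self):
        o1 = GeneOrder("g1", [("a", 1), ("x", 1), ("b", 1)])
        o2 = GeneOrder("g2", [("a", 1), ("b", 1)])
        secs = merge_sections([o1, o2])
        assert ("x",) in partition_of(secs)

    def test_input_order_and_rotation_invariance(self):
        rng = random.Random(5)
        o1 = GeneOrder("g1", [(f"u{i}", 1) for i in range(8)])
        units2 = [("u0", 1), ("u1", 1), ("u2", -1), ("u3", 1),
                  ("u4", 1), ("u7", -1), ("u6", -1), ("u5", -1)]
        o2 = GeneOrder("g2", units2)
        base = partition_of(merge_sections([o1, o2]))
        for _ in range(6):
            a = o1.rotate(rng.randrange(8))
            b = o2.rotate(rng.randrange(8))
            pair = [a, b] if rng.random() < 0.5 else [b, a]
            assert partition_of(merge_sections(pair)) == base

    def test_refinement_monotonicity(self):
        """Adding a genome can only split sections, never merge them."""
        rng = random.Random(17)
        o1 = GeneOrder("g1", [(f"u{i}", 1) for i in range(10)])
        o2 = GeneOrder("g2", [("u0", 1), ("u1", 1), ("u2", 1), ("u3", 1),
                              ("u6", -1), ("u5", -1), ("u4", -1),
                              ("u7", 1), ("u8", 1), ("u9", 1)])
        o3 = random_signed_order(rng, 10, "g3")
        two = partition_of(merge_sections([o1, o2]))
        three = partition_of(merge_sections([o1, o2, o3]))
        blocks2 = {frozenset(b) for b in two}
        for block in three:
            assert any(set(block) <= b for b in blocks2)

    def test_contiguity_in_every_genome(self):
        rng = random.Random(23)
        orders = [GeneOrder("g1", [(f"u{i}", 1) for i in range(12)])]
        orders.append(GeneOrder("g2", [("u0", 1), ("u1", 1), ("u5", -1),
                                       ("u4", -1), ("u3", -1), ("u2", -1),
                                       ("u6", 1), ("u7", 1), ("u8", 1),
                                       ("u9", 1), ("u10", 1), ("u11", 1)]))
        secs = merge_sections(orders)
        for o in orders:
            section_order(o, secs)  # raises on any contiguity violation


class TestSectionOrder:
    def test_reference_genome_all_positive(self):
        o1 = GeneOrder("g1", [("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        o2 = GeneOrder("g2", [("a", 1), ("b", 1), ("d", -1), ("c", -1)])
        secs = merge_sections([o1, o2])
        so1 = section_order(o1, secs)
        assert all(sign == 1 for _, sign in so1)

    def test_inverted_block_sign_flips(self):
        o1 = GeneOrder("g1", [("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", 1)])
        o2 = GeneOrder("g2", [("a", 1), ("c", -1), ("b", -1), ("d", 1), ("e", 1)])
        secs = merge_sections([o1, o2])
        so2 = dict(section_order(o2, secs))
        bc_sec = next(s for s in secs if set(s.labels) == {"b", "c"})
        assert so2[bc_sec.id] == -1

    def test_noncontiguous_members_hard_error(self):
        o1 = GeneOrder("g1", [("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        o2 = GeneOrder("g2", [("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        secs = merge_sections([o1, o2])
        scattered = GeneOrder("g3", [("a", 1), ("c", 1), ("b", 1), ("d", 1)])
        with pytest.raises(ValueError):
            section_order(scattered, secs)


class TestBreakpointDistance:
    def test_identical_orders(self):
        o = GeneOrder("g", [("a", 1), ("b", -1), ("c", 1)])
        assert breakpoint_distance(o, o) == 0

    def test_single_inversion_is_two(self):
        o1 = GeneOrder("g1", [(f"u{i}", 1) for i in range(8)])
        o2 = GeneOrder("g2", [("u0", 1), ("u1", 1), ("u4", -1), ("u3", -1),
                              ("u2", -1), ("u5", 1), ("u6", 1), ("u7", 1)])
        assert breakpoint_distance(o1, o2) == 2

    def test_matches_set_difference_oracle(self):
        rng = random.Random(99)
        for n in (4, 7, 12):
            for _ in range(20):
                a = random_signed_order(rng, n, "a")
                b = random_signed_order(rng, n, "b")
                assert breakpoint_distance(a, b) == brute_force_breakpoints(
                    list(a.units), list(b.units))

    def test_semimetric_properties(self):
        rng = random.Random(3)
        for _ in range(10):
            a = random_signed_order(rng, 9, "a")
            b = random_signed_order(rng, 9, "b")
            d_ab = breakpoint_distance(a, b)
            assert d_ab >= 0
            assert d_ab == breakpoint_distance(b, a)
        a = random_signed_order(rng, 9, "a")
        rot = a.rotate(4)
        refl = a.reflect()
        assert breakpoint_distance(a, rot) == 0
        assert breakpoint_distance(a, refl) == 0
        assert cyclic_signed_equal(a, rot) and cyclic_signed_equal(a, refl)

    def test_too_few_shared_units(self):
        a = GeneOrder("a", [("x", 1), ("y", 1)])
        b = GeneOrder("b", [("x", 1), ("z", 1)])
        with pytest.raises(ValueError):
            breakpoint_distance(a, b)


class TestMapEventsOnTree:
    def test_all_tips_identical(self):
        o = [("a", 1), ("b", 1), ("c", 1), ("d", 1)]
        orders = {t: GeneOrder(t, o) for t in ("t1", "t2", "t3")}
        assert map_events_on_tree(orders, "((t1,t2),t3);") == []

    def test_three_taxon_inversion_on_pendant_edge(self):
        base = [("a", 1), ("b", 1), ("c", 1), ("d", 1)]
        inv = [("a", 1), ("c", -1), ("b", -1), ("d", 1)]
        orders = {"t1": GeneOrder("t1", base), "t2": GeneOrder("t2", base),
                  "t3": GeneOrder("t3", inv)}
        changes = map_events_on_tree(orders, "((t1,t2),t3);")
        pendant = next(c for c in changes if c.clade == frozenset({"t3"}))
        lost_labels = {frozenset((u[0], v[0])) for u, v in pendant.lost}
        assert lost_labels == {frozenset(("a", "b")), frozenset(("c", "d"))}
        gained_labels = {frozenset((u[0], v[0])) for u, v in pendant.gained}
        assert gained_labels == {frozenset(("a", "c")), frozenset(("b", "d"))}

    def test_missing_tip_order_rejected(self):
        orders = {"t1": GeneOrder("t1", [("a", 1), ("b", 1)])}
        with pytest.raises(ValueError):
            map_events_on_tree(orders, "((t1,t2),t3);")
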