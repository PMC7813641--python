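import random
from collections import Counter

import pytest

from mitoarchitect.genome_io import CircularGenome, revcomp
from mitoarchitect.sir_scan import (PalindromeHit, PalindromeParams,
                                    build_sir_tables, call_repeat_types,
                                    classify_hexamer, filter_stem_gt_loop,
                                    find_palindromes)
from mitoarchitect.synth_data import SirPlan, SynthConfig, generate_genome

from conftest import random_seq
from oracles import brute_force_palindromes


def hit_key(h):
    return (h.left_arm[0], h.stem_len, h.loop_len, h.mismatches)


class TestFindPalindromes:
    def test_planted_perfect_hairpin(self):
        g = CircularGenome("g", "AGGCGCCTTTGGCGCCA", "linear")
        hits = find_palindromes(g, PalindromeParams(max_mismatch=0))
        assert len(hits) == 1
        h = hits[0]
        assert (h.left_arm, h.right_arm) == ((1, 7), (10, 16))
        assert (h.stem_len, h.loop_len, h.mismatches) == (6, 3, 0)

    def test_planted_one_mismatch(self):
        g = CircularGenome("g", "AGGCGCCTTTGGCACCA", "linear")
        hits = find_palindromes(g, PalindromeParams(max_mismatch=1))
        assert len(hits) == 1
        assert (hits[0].stem_len, hits[0].loop_len, hits[0].mismatches) == (6, 3, 1)

    def test_at_pairing(self):
        g = CircularGenome("g", "AAAAAAGGTTTTTT", "linear")
        hits = find_palindromes(g, PalindromeParams(max_mismatch=0))
        assert len(hits) == 1
        assert (hits[0].stem_len, hits[0].loop_len) == (6, 2)
        assert hits[0].hexamer == "AAAAAA"

    @pytest.mark.parametrize("circular", [False, True])
    @pytest.mark.parametrize("mm", [0, 1])
    def test_matches_bruteforce_oracle(self, circular, mm):
        """The scanner equals exhaustive triple enumeration on random
        sequences (the core correctness guarantee)."""
        rng = random.Random(991 + mm + 2 * circular)
        for _ in range(6):
            n = rng.choice([150, 400, 900, 2000])
            seq = random_seq(rng, n, gc=rng.choice([0.3, 0.5]))
            g = CircularGenome("g", seq, "circular" if circular else "linear")
            params = PalindromeParams(min_stem=5, max_stem=60, max_loop=9,
                                      max_mismatch=mm)
            mine = sorted(hit_key(h) for h in find_palindromes(g, params))
            ref = brute_force_palindromes(seq, 5, 60, 9, mm, circular)
            assert mine == ref

    def test_every_hit_satisfies_params(self, rng):
        params = PalindromeParams()
        for _ in range(5):
            seq = random_seq(rng, 1500, gc=0.5)
            g = CircularGenome("g", seq, "circular")
            for h in find_palindromes(g, params):
                assert params.min_stem <= h.stem_len <= params.max_stem
                assert 0 <= h.loop_len <= params.max_loop
                assert h.mismatches <= params.max_mismatch
                left = g.fetch(*h.left_arm)
                right = g.fetch(h.right_arm[0], h.right_arm[0] + h.stem_len)
                mism = sum(1 for x, y in zip(revcomp(left), right) if x != y)
                assert mism == h.mismatches

    def test_rotation_invariance(self, rng):
        seq = random_seq(rng, 800, gc=0.5)
        g = CircularGenome("g", seq, "circular")
        base = Counter((h.stem_len, h.loop_len, h.mismatches, h.hexamer)
                       for h in find_palindromes(g))
        for shift in (137, 411):
            g2 = CircularGenome("g", seq[shift:] + seq[:shift], "circular")
            rot = Counter((h.stem_len, h.loop_len, h.mismatches, h.hexamer)
                          for h in find_palindromes(g2))
            assert rot == base

    def test_strand_duality(self, rng):
        """Scanning the reverse complement yields the same hits at mirrored
        coordinates. For perfect hits the loop-adjacent hexamer is strand-
        invariant (the new left arm is the reverse complement of the old
        right arm, which equals the old left arm); only hits whose mismatch
        falls inside the classifying window may change class."""
        seq = random_seq(rng, 1000, gc=0.5)
        n = len(seq)
        fwd = find_palindromes(CircularGenome("g", seq, "linear"))
        rev = find_palindromes(CircularGenome("g", revcomp(seq), "linear"))
        fc = Counter((h.left_arm[0], h.stem_len, h.loop_len, h.mismatches)
                     for h in fwd)
        rc = Counter((n - h.right_arm[1], h.stem_len, h.loop_len, h.mismatches)
                     for h in rev)
        assert fc == rc
        perfect_f = Counter(h.hexamer for h in fwd if h.mismatches == 0)
        perfect_r = Counter(h.hexamer for h in rev if h.mismatches == 0)
        assert perfect_f == perfect_r

    def test_loop_budget_monotonicity(self, rng):
        """Raising max_loop or max_mismatch never shrinks covered bp."""
        seq = random_seq(rng, 1200, gc=0.5)
        g = CircularGenome("g", seq, "linear")

        def coverage(params):
            cov = set()
            for h in find_palindromes(g, params):
                cov.update(range(h.span[0], h.span[0] + h.span_len))
            return cov

        base = coverage(PalindromeParams(min_stem=5, max_loop=4, max_mismatch=0))
        assert base <= coverage(PalindromeParams(min_stem=5, max_loop=8, max_mismatch=0))
        assert base <= coverage(PalindromeParams(min_stem=5, max_loop=4, max_mismatch=1))

    def test_empty_on_no_hits(self):
        g = CircularGenome("g", "A" * 30, "linear")
        assert find_palindromes(g, PalindromeParams(max_mismatch=0)) == []


class TestFilterAndClassify:
    def test_stem_gt_loop_boundaries(self):
        def mk(stem, loop):
            return PalindromeHit("g", (0, stem), (stem + loop, 2 * stem + loop),
                                 loop, stem, 0)
        kept = filter_stem_gt_loop([mk(6, 3), mk(6, 8), mk(7, 7)])
        assert [(h.stem_len, h.loop_len) for h in kept] == [(6, 3)]

    def test_hexamer_is_loop_adjacent_left_arm(self):
        seq = "TAGGCGCC" + "AAA" + revcomp("TAGGCGCC")
        g = CircularGenome("g", seq, "linear")
        hits = find_palindromes(g, PalindromeParams(max_mismatch=0))
        h = next(h for h in hits if h.stem_len == 8)
        assert classify_hexamer(h, g) == "GGCGCC"

    def test_planted_family_uses_left_arm_strand(self, planted_genome):
        """An AAAAAA-family plant classifies as AAAAAA, never TTTTTT."""
        genome, _, truth = planted_genome
        hits = find_palindromes(genome)
        keys = {(h.left_arm, h.right_arm): h.hexamer for h in hits}
        for p in truth.planted_sirs:
            if p.hexamer == "AAAAAA":
                assert keys[(p.left_arm, p.right_arm)] == "AAAAAA"

    def test_ambiguous_on_n(self):
        g = CircularGenome("g", "GGCNCCTTTGGNGCC", "linear")
        h = PalindromeHit("g", (0, 6), (9, 15), 3, 6, 1)
        assert classify_hexamer(h, g) == "ambiguous"


class TestRepeatTypes:
    def test_threshold_boundary_at_ten(self):
        hits = ([PalindromeHit("g", (i * 200, i * 200 + 6),
                               (i * 200 + 8, i * 200 + 14), 2, 6, 0, "GGATCC")
                 for i in range(10)]
                + [PalindromeHit("g", (5000 + i * 200, 5000 + i * 200 + 6),
                                 (5000 + i * 200 + 8, 5000 + i * 200 + 14),
                                 2, 6, 0, "CCGTAC")
                   for i in range(9)])
        assert call_repeat_types(hits, threshold=10) == {"GGATCC"}

    def test_empty_roster(self):
        assert call_repeat_types([]) == set()

    def test_planted_roster_recovery(self, planted_genome):
        genome, _, truth = planted_genome
        hits = filter_stem_gt_loop(find_palindromes(genome))
        roster = call_repeat_types(hits)
        assert "GGCGCC" in roster
        counts = Counter(h.hexamer for h in hits)
        assert counts["GGCGCC"] >= 12


class TestSirTables:
    def test_region_conservation(self, planted_genome):
        from mitoarchitect.genome_io import partition_regions

        genome, features, _ = planted_genome
        part = partition_regions(genome, features)
        hits = filter_stem_gt_loop(find_palindromes(genome))
        table = build_sir_tables({genome.id: hits}, {genome.id: part})
        row = table.region_stats.loc[genome.id]
        assert row["n_total"] == row["n_coding"] + row["n_intergenic"]
        assert row["bp_total"] == row["bp_coding"] + row["bp_intergenic"]
        assert row["n_total"] == table.counts[genome.id].sum()

    def test_union_scope_keeps_subthreshold_counts(self):
        """A class repeat-level in one genome is reported for all genomes,
        at each genome's own count."""
        def mk(gid, n, hexamer):
            return [PalindromeHit(gid, (i * 200, i * 200 + 6),
                                  (i * 200 + 8, i * 200 + 14), 2, 6, 0, hexamer)
                    for i in range(n)]
        table = build_sir_tables({"g1": mk("g1", 12, "GGCGCC"),
                                  "g2": mk("g2", 2, "GGCGCC")},
                                 roster_scope="union")
        assert table.counts.loc["GGCGCC", "g1"] == 12
        assert table.counts.loc["GGCGCC", "g2"] == 2

    def test_planted_region_truth(self, planted_genome):
        from mitoarchitect.genome_io import partition_regions

        genome, features, truth = planted_genome
        part = partition_regions(genome, features)
        hits = filter_stem_gt_loop(find_palindromes(genome))
        planted_regions = Counter(p.region for p in truth.planted_sirs)
        keys = {(h.left_arm, h.right_arm) for h in hits}
        for p in truth.planted_sirs:
            assert (p.left_arm, p.right_arm) in keys
            span_len = 2 * p.stem_len + p.loop_len
            assert part.midpoint_class(p.left_arm[0],
                                       p.left_arm[0] + span_len) == p.region
        assert planted_regions["coding"] == 6
        assert planted_regions["intergenic"] == 12
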