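import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ladscreen import screen_stats as ss
from ladscreen.formats_io import GeneModel, Insertion

from oracles import assign_insertions_literal, bh_step_up, fisher_exact_enumeration


class TestPools:
    def test_dedupe_collapses_identical_triples(self):
        ins = [Insertion("chr1", 10, "+")] * 2 + [Insertion("chr1", 10, "-")]
        pool = ss.dedupe_pool(ins)
        assert pool.size == 2  # same position, opposite orientation: both kept

    def test_dedupe_is_order_invariant(self, rng):
        ins = [
            Insertion("chr%d" % rng.integers(1, 3), int(rng.integers(0, 50)), "+")
            for _ in range(100)
        ]
        a = ss.dedupe_pool(ins)
        perm = [ins[i] for i in rng.permutation(len(ins))]
        b = ss.dedupe_pool(perm)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.chrom, b.chrom)
        assert np.array_equal(a.orientation, b.orientation)

    def test_dedupe_rejects_mixed_pool_labels(self):
        ins = [Insertion("chr1", 1, "+", "A"), Insertion("chr1", 2, "+", "B")]
        with pytest.raises(ValueError, match="multiple pools"):
            ss.dedupe_pool(ins)

    def test_merge_disjoint_and_identical_pools(self):
        p1 = ss.dedupe_pool([Insertion("chr1", i, "+") for i in range(5)], "H")
        p2 = ss.dedupe_pool([Insertion("chr1", i, "+") for i in range(100, 107)], "H")
        assert ss.merge_pools(p1, p2).size == 12
        assert ss.merge_pools(p1, p1).size == p1.size

    def test_merge_equals_dedupe_of_concatenation(self, rng):
        raw1 = [Insertion("chr1", int(rng.integers(0, 30)), "+") for _ in range(40)]
        raw2 = [Insertion("chr1", int(rng.integers(0, 30)), "+") for _ in range(40)]
        merged = ss.merge_pools(ss.dedupe_pool(raw1), ss.dedupe_pool(raw2))
        direct = ss.dedupe_pool(raw1 + raw2)
        assert np.array_equal(merged.pos, direct.pos)


class TestCountingRegions:
    def test_non_overlapping_genes_keep_full_regions(self, tiny_models):
        regions = ss.build_counting_regions(tiny_models)
        assert regions.intervals("gA") == [("chr1", 1_000, 5_000)]

    def test_partial_overlap_is_removed_from_both(self):
        models = [
            GeneModel("A", "chr1", "+", 0, 100, 60),
            GeneModel("B", "chr1", "+", 50, 150, 60),
        ]
        regions = ss.build_counting_regions(models)
        assert regions.intervals("A") == [("chr1", 0, 50)]
        assert regions.intervals("B") == [("chr1", 100, 150)]

    def test_nested_gene_loses_everything(self):
        models = [
            GeneModel("outer", "chr1", "+", 0, 1_000, 600),
            GeneModel("inner", "chr1", "-", 200, 800, 300),
        ]
        regions = ss.build_counting_regions(models)
        assert regions.intervals("inner") == []
        assert regions.intervals("outer") == [("chr1", 0, 200), ("chr1", 800, 1_000)]

    def test_counts_match_literal_assignment_oracle(self, rng):
        models = [
            GeneModel("A", "chr1", "+", 0, 100, 60),
            GeneModel("B", "chr1", "+", 50, 150, 60),
            GeneModel("C", "chr1", "-", 300, 400, 60),
            GeneModel("D", "chr2", "+", 0, 500, 60),
        ]
        triples = [
            ("chr%d" % rng.integers(1, 3), int(rng.integers(0, 500)),
             "+" if rng.random() < 0.5 else "-")
            for _ in range(400)
        ]
        pool = ss.dedupe_pool([Insertion(*t) for t in triples])
        regions = ss.build_counting_regions(models)
        counts, total = ss.count_sense_insertions(pool, regions)
        uniq = {(c, p, o) for c, p, o in zip(pool.chrom, pool.pos, pool.orientation)}
        expected = assign_insertions_literal(uniq, models)
        assert counts.to_dict() == expected
        assert total == sum(expected.values())  # conservation

    def test_sense_only_orientation_rule(self, tiny_models):
        regions = ss.build_counting_regions(tiny_models)
        sense = ss.dedupe_pool([Insertion("chr1", 2_000, "+")])
        anti = ss.dedupe_pool([Insertion("chr1", 2_000, "-")])
        assert ss.count_sense_insertions(sense, regions)[0]["gA"] == 1
        assert ss.count_sense_insertions(anti, regions)[0]["gA"] == 0


class TestMutationalIndex:
    def test_symmetric_counts_give_unity(self):
        assert ss.mutational_index(10, 110, 10, 110) == 1.0

    def test_direct_evaluation_of_odds_ratio(self):
        assert ss.mutational_index(20, 120, 5, 105) == pytest.approx(4.0)

    def test_zero_count_limits(self):
        assert ss.mutational_index(0, 100, 7, 100) == 0.0
        assert ss.mutational_index(7, 100, 0, 100) == math.inf
        assert math.isnan(ss.mutational_index(0, 100, 0, 100))

    def test_degenerate_pool_flagged_nan(self):
        assert math.isnan(ss.mutational_index(100, 100, 5, 100))

    def test_reciprocal_identity_on_random_counts(self, rng):
        for _ in range(1_000):
            t_h, t_l = rng.integers(10, 1_000, 2)
            a = int(rng.integers(1, t_h))
            b = int(rng.integers(1, t_l))
            prod = ss.mutational_index(a, t_h, b, t_l) * ss.mutational_index(b, t_l, a, t_h)
            assert prod == pytest.approx(1.0, rel=1e-12)


class TestFisher:
    def test_modal_table_has_p_one(self):
        assert ss.fisher_two_sided(5, 5, 5, 5) == 1.0

    def test_zero_margin_has_p_one(self):
        assert ss.fisher_two_sided(0, 0, 3, 7) == 1.0
        assert ss.fisher_two_sided(0, 5, 0, 7) == 1.0

    def test_matches_enumeration_oracle_on_reference_table(self):
        assert ss.fisher_two_sided(12, 48, 3, 57) == pytest.approx(
            fisher_exact_enumeration(12, 48, 3, 57), abs=1e-12
        )

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            assert ss.fisher_two_sided(a, b, c, d) == pytest.approx(
                fisher_exact_enumeration(a, b, c, d), abs=1e-12
            )

    def test_matches_scipy_reference(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            assert ss.fisher_two_sided(a, b, c, d) == pytest.approx(
                sps.fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-11
            )

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            p = ss.fisher_two_sided(a, b, c, d)
            assert ss.fisher_two_sided(c, d, a, b) == pytest.approx(p, abs=1e-13)
            assert ss.fisher_two_sided(b, a, d, c) == pytest.approx(p, abs=1e-13)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            ss.fisher_two_sided(-1, 2, 3, 4)


class TestBH:
    def test_constant_ratio_vector(self):
        np.testing.assert_allclose(
            ss.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_allclose(ss.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(ss.bh_adjust(p), bh_step_up(p), atol=1e-12)

    def test_preserves_input_order(self, rng):
        p = rng.random(25)
        adj = ss.bh_adjust(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(ss.bh_adjust(p[perm]), adj[perm], atol=1e-12)


def _toy_screen():
    models = [
        GeneModel("g1", "chr1", "+", 0, 1_000, 600),
        GeneModel("g2", "chr1", "+", 2_000, 3_000, 600),
        GeneModel("g3", "chr1", "-", 5_000, 6_000, 600),
    ]
    regions = ss.build_counting_regions(models)
    rng = np.random.default_rng(7)
    high = ss.dedupe_pool(
        [Insertion("chr1", int(p), "+") for p in rng.integers(0, 1_000, 60)]
        + [Insertion("chr1", int(p), "+") for p in rng.integers(2_000, 3_000, 25)]
        + [Insertion("chr1", int(p), "-") for p in rng.integers(5_000, 6_000, 40)],
        "HIGH",
    )
    low = ss.dedupe_pool(
        [Insertion("chr1", int(p), "+") for p in rng.integers(0, 1_000, 20)]
        + [Insertion("chr1", int(p), "+") for p in rng.integers(2_000, 3_000, 28)]
        + [Insertion("chr1", int(p), "-") for p in rng.integers(5_000, 6_000, 42)],
        "LOW",
    )
    return high, low, regions


class TestScoreScreen:
    def test_swapping_pools_inverts_mi_and_keeps_p(self):
        high, low, regions = _toy_screen()
        fwd = ss.score_screen(high, low, regions).set_index("gene_id")
        rev = ss.score_screen(low, high, regions).set_index("gene_id")
        for g in fwd.index:
            assert rev.loc[g, "mi"] == pytest.approx(1 / fwd.loc[g, "mi"], rel=1e-12)
            assert rev.loc[g, "p"] == pytest.approx(fwd.loc[g, "p"], abs=1e-12)
        swapped = {"repressor": "activator", "activator": "repressor", "ns": "ns"}
        assert list(rev["hit_class"]) == [swapped[c] for c in fwd["hit_class"]]

    def test_fcpv_never_below_raw_p(self):
        high, low, regions = _toy_screen()
        scores = ss.score_screen(high, low, regions)
        assert (scores["fcpv"] >= scores["p"] - 1e-15).all()

    def test_empty_pool_is_an_error(self):
        high, _low, regions = _toy_screen()
        empty = ss.dedupe_pool([], "LOW")
        with pytest.raises(ValueError, match="empty"):
            ss.score_screen(high, empty, regions)

    def test_all_sense_total_counts_ambiguous_insertions(self):
        models = [
            GeneModel("A", "chr1", "+", 0, 100, 60),
            GeneModel("B", "chr1", "+", 50, 150, 60),
        ]
        regions = ss.build_counting_regions(models)
        # one unambiguous sense insertion in A, one in the shared 50-100 span
        pool = ss.dedupe_pool(
            [Insertion("chr1", 10, "+"), Insertion("chr1", 70, "+")], "H"
        )
        assert ss.count_sense_insertions(pool, regions)[1] == 1
        assert ss.count_all_sense(pool, regions) == 2


class TestOverlapAndEnrichment:
    def _scores(self, hits_by_class):
        rows = []
        for cls, genes in hits_by_class.items():
            for g in genes:
                rows.append((g, 0.01 if cls != "ns" else 0.5, cls))
        return pd.DataFrame(rows, columns=["gene_id", "fcpv", "hit_class"])

    def test_identical_and_disjoint_hit_sets(self):
        a = self._scores({"repressor": ["g1", "g2"]})
        assert ss.screen_overlap(a, a)["all"]["shared_fraction"] == 1.0
        b = self._scores({"repressor": ["g3"]})
        assert ss.screen_overlap(a, b)["all"]["shared_fraction"] == 0.0

    def test_fractional_overlap(self):
        a = self._scores({"repressor": ["g1", "g2", "g3"]})
        b = self._scores({"repressor": ["g3", "g4"]})
        assert ss.screen_overlap(a, b)["all"]["shared_fraction"] == pytest.approx(0.25)

    def test_enrichment_fold_for_hits_inside_set(self):
        background = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(50)}
        hits = {f"g{i}" for i in range(10)}  # all inside the set
        res = ss.set_enrichment(hits, background, gene_set)
        assert res.fold == pytest.approx(2.0)

    def test_enrichment_matches_oracle_counts(self):
        background = {f"g{i}" for i in range(1_000)}
        gene_set = {f"g{i}" for i in range(40)}
        hits = {f"g{i}" for i in range(20)} | {f"g{i}" for i in range(500, 580)}
        res = ss.set_enrichment(hits, background, gene_set)
        # 20 of 100 hits in the set vs 40 of 1000 background
        assert res.n_hits_in_set == 20 and res.n_hits == 100
        assert res.fold == pytest.approx((20 / 100) / (40 / 1_000))
        assert res.p == pytest.approx(
            fisher_exact_enumeration(20, 80, 20, 880), abs=1e-12
        )

    def test_hits_must_be_subset_of_background(self):
        with pytest.raises(ValueError):
            ss.set_enrichment({"x"}, {"a", "b"}, {"a"})
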