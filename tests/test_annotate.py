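"""CRE enrichment, gene linking, differential expression, TF annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopdiff import (
    ExpressionTable,
    Genome,
    GenomicInterval,
    LoopCall,
    anchor_cre_overlap,
    annotate_tf_anchored,
    differential_expression,
    link_genes,
    permutation_enrichment,
)

RES = 10_000
GENOME = Genome([("chr1", 5_000_000)])


def _loop(b1: int, b2: int, chrom: str = "chr1") -> LoopCall:
    return LoopCall(
        GenomicInterval(chrom, b1 * RES, (b1 + 1) * RES),
        GenomicInterval(chrom, b2 * RES, (b2 + 1) * RES),
    )


class TestAnchorCreOverlap:
    def test_tiling_cres_give_one(self):
        loops = [_loop(10, 40), _loop(100, 200)]
        cres = [GenomicInterval("chr1", 0, 5_000_000)]
        assert anchor_cre_overlap(loops, cres) == 1.0

    def test_empty_cre_set_gives_zero(self):
        assert anchor_cre_overlap([_loop(10, 40)], []) == 0.0

    def test_either_anchor_rule(self):
        loops = [_loop(10, 40)]
        cre_on_anchor2 = [GenomicInterval("chr1", 400_000, 401_000)]
        assert anchor_cre_overlap(loops, cre_on_anchor2) == 1.0

    def test_anchor_level_statistic(self):
        loops = [_loop(10, 40)]
        cre_on_anchor2 = [GenomicInterval("chr1", 400_000, 401_000)]
        assert anchor_cre_overlap(loops, cre_on_anchor2,
                                  statistic="anchors") == 0.5


class TestPermutationEnrichment:
    def test_tiling_cres_p_is_one(self):
        loops = [_loop(10, 40), _loop(80, 120)]
        cres = [GenomicInterval("chr1", 0, 5_000_000)]
        res = permutation_enrichment(loops, cres, GENOME, n_perm=50, seed=0)
        assert res.observed_fraction == 1.0
        assert (res.null_fractions == 1.0).all()
        assert res.p_empirical == 1.0

    def test_empty_cres_p_is_one(self):
        res = permutation_enrichment([_loop(10, 40)], [], GENOME,
                                     n_perm=50, seed=0)
        assert res.observed_fraction == 0.0
        assert res.p_empirical == 1.0

    def test_add_one_floor_and_determinism(self):
        rng = np.random.default_rng(0)
        cres = [
            GenomicInterval("chr1", int(s), int(s) + 2000)
            for s in rng.integers(0, 4_990_000, 50)
        ]
        loops = [_loop(10, 40), _loop(100, 200), _loop(300, 450)]
        r1 = permutation_enrichment(loops, cres, GENOME, n_perm=200, seed=5)
        r2 = permutation_enrichment(loops, cres, GENOME, n_perm=200, seed=5)
        assert r1.p_empirical == r2.p_empirical
        np.testing.assert_array_equal(r1.null_fractions, r2.null_fractions)
        assert r1.p_empirical >= 1.0 / 201.0

    def test_concentrated_cres_strongly_enriched(self):
        loops = [_loop(10 + 30 * k, 200 + 30 * k) for k in range(10)]
        cres = [
            GenomicInterval("chr1", lp.anchor1.start + 4000,
                            lp.anchor1.start + 5000)
            for lp in loops
        ]
        res = permutation_enrichment(loops, cres, GENOME, n_perm=500, seed=1)
        assert res.observed_fraction == 1.0
        assert res.p_empirical <= 0.01

    def test_anchor_wider_than_chromosome_rejected(self):
        tiny = Genome([("chr1", 5_000)])
        lp = LoopCall(
            GenomicInterval("chr1", 0, 6_000),  # wider than the chromosome
            GenomicInterval("chr1", 7_000, 9_000),
        )
        with pytest.raises(ValueError):
            permutation_enrichment(
                [lp], [GenomicInterval("chr1", 0, 10_000)], tiny, n_perm=10,
                seed=0,
            )


class TestLinkGenes:
    def test_flank_reaches_anchor(self):
        # anchor [100000,110000); gene [111000,115000) + 3 kb flank starts
        # at 108000 -> linked
        loops = [_loop(10, 60)]
        gene = GenomicInterval("chr1", 111_000, 115_000, name="g1")
        out = link_genes(loops, [gene], flank=3000)
        assert out["gene"].tolist() == ["g1"]

    def test_flank_too_short_not_linked(self):
        loops = [_loop(10, 60)]
        gene = GenomicInterval("chr1", 114_000, 118_000, name="g1")
        out = link_genes(loops, [gene], flank=3000)
        assert out.empty

    def test_other_chromosome_not_linked(self):
        loops = [_loop(10, 60)]
        gene = GenomicInterval("chr2", 100_000, 104_000, name="g1")
        out = link_genes(loops, [gene], flank=3000)
        assert out.empty

    def test_zero_flank_is_plain_intersection(self):
        loops = [_loop(10, 60)]
        inside = GenomicInterval("chr1", 105_000, 106_000, name="in")
        outside = GenomicInterval("chr1", 110_000, 111_000, name="out")
        got = link_genes(loops, [inside, outside], flank=0)
        assert got["gene"].tolist() == ["in"]

    def test_linked_set_monotone_in_flank(self):
        rng = np.random.default_rng(4)
        loops = [_loop(int(b), int(b) + 50) for b in rng.integers(10, 400, 5)]
        genes = [
            GenomicInterval("chr1", int(s), int(s) + 2_000, name=f"g{k}")
            for k, s in enumerate(rng.integers(0, 4_900_000, 200))
        ]
        prev: set = set()
        for flank in (0, 1_000, 3_000, 10_000, 50_000):
            cur = set(link_genes(loops, genes, flank=flank)["gene"])
            assert prev <= cur
            prev = cur


class TestDifferentialExpression:
    def _table(self, rows: dict[str, list[float]]) -> ExpressionTable:
        values = pd.DataFrame(
            rows, index=[f"s{k}" for k in range(8)]
        ).T
        groups = {f"s{k}": ("A" if k < 4 else "B") for k in range(8)}
        return ExpressionTable(values, groups)

    def test_identical_values_not_significant(self):
        t = self._table({"g": [5.0] * 8})
        out = differential_expression(t, "A", "B")
        assert out.loc["g", "log2fc"] == 0.0
        assert out.loc["g", "p_value"] == 1.0
        assert not out.loc["g", "significant"]

    def test_fourfold_gene_matches_formula(self):
        a = [10.0, 12.0, 11.0, 11.0]
        b = [2.0, 3.0, 2.5, 2.5]
        t = self._table({"g": a + b})
        out = differential_expression(t, "A", "B")
        lfc_direct = np.log2((np.mean(a) + 0.1) / (np.mean(b) + 0.1))
        t_direct, p_direct = stats.ttest_ind(a, b, equal_var=True)
        assert out.loc["g", "log2fc"] == pytest.approx(lfc_direct)
        assert out.loc["g", "log2fc"] == pytest.approx(2.1, abs=0.05)
        assert out.loc["g", "p_value"] == pytest.approx(p_direct)
        assert bool(out.loc["g", "significant"])

    def test_fold_change_floor_blocks_significance(self):
        # tiny but consistent shift: p tiny, |log2FC| < 1 -> not significant
        a = [10.0, 10.01, 9.99, 10.0]
        b = [9.0, 9.01, 8.99, 9.0]
        t = self._table({"g": a + b})
        out = differential_expression(t, "A", "B")
        assert out.loc["g", "p_value"] < 1e-6
        assert abs(out.loc["g", "log2fc"]) < 1.0
        assert not out.loc["g", "significant"]

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame({"s0": [1.0], "s1": [2.0]}, index=["g"])
        t = ExpressionTable(values, {"s0": "A", "s1": "B"})
        with pytest.raises(ValueError):
            differential_expression(t, "A", "B")


class TestAnnotateTfAnchored:
    peaks1 = [GenomicInterval("chr1", 100_000, 101_000)]  # on anchor1 of (10,60)
    peaks2 = [GenomicInterval("chr1", 100_500, 101_500)]  # also anchor1

    def test_both_sets_on_one_anchor_kept_under_any_anchor_rule(self):
        kept = annotate_tf_anchored(
            [_loop(10, 60)], [self.peaks1, self.peaks2], resolution=RES
        )
        assert len(kept) == 1

    def test_missing_factor_drops_loop(self):
        far = [GenomicInterval("chr1", 3_000_000, 3_001_000)]
        kept = annotate_tf_anchored([_loop(10, 60)], [self.peaks1, far],
                                    resolution=RES)
        assert kept == []

    def test_both_anchor_mode_requires_each_anchor(self):
        kept = annotate_tf_anchored(
            [_loop(10, 60)], [self.peaks1], resolution=RES,
            mode="both_anchors",
        )
        assert kept == []

    def test_excluded_loop_removed(self):
        kept = annotate_tf_anchored(
            [_loop(10, 60)], [self.peaks1],
            exclude_loops=[_loop(10, 60)], resolution=RES,
        )
        assert kept == []

    def test_exclusion_respects_tolerance(self):
        kept = annotate_tf_anchored(
            [_loop(10, 60)], [self.peaks1],
            exclude_loops=[_loop(13, 60)], resolution=RES, tol_bins=1,
        )
        assert len(kept) == 1
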