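"""Pairwise differential loops, matching, and the two-level consensus."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from loopdiff import (
    GenomicInterval,
    LoopCall,
    LoopSet,
    compute_expected,
    gained_loops_for_sample,
    match_loops,
    pairwise_differential,
    subtype_enriched_loops,
)
from loopdiff.differential import GainedLoop, PairwiseDifferential

from conftest import make_decay_map

RES = 10_000


def _loop(b1: int, b2: int, chrom: str = "chrT", q: float = 0.01,
          sample_id=None) -> LoopCall:
    return LoopCall(
        GenomicInterval(chrom, b1 * RES, (b1 + 1) * RES),
        GenomicInterval(chrom, b2 * RES, (b2 + 1) * RES),
        q_value=q, sample_id=sample_id,
    )


class TestPairwiseDifferential:
    def test_identical_maps_give_empty_set(self):
        planted = {(20, 35): 10.0}
        cmap = make_decay_map(n_bins=80, scale=200.0, planted=planted)
        prof = compute_expected(cmap)
        loops = LoopSet([_loop(20, 35)], RES, "x")
        pw = pairwise_differential(loops, cmap, cmap, prof, prof)
        assert pw.loops == []

    def test_loop_only_in_x_detected(self):
        planted = {(20, 35): 10.0}
        map_x = make_decay_map(n_bins=80, scale=200.0, planted=planted)
        map_y = make_decay_map(n_bins=80, scale=200.0)
        prof_x = compute_expected(map_x)
        prof_y = compute_expected(map_y)
        loops = LoopSet([_loop(20, 35)], RES, "x")
        pw = pairwise_differential(loops, map_x, map_y, prof_x, prof_y,
                                   sample_x="x", sample_y="y")
        assert len(pw.loops) == 1
        assert pw.loops[0].bins(RES) == (20, 35)
        assert pw.loops[0].q_value < 1e-3
        # direct conditional-binomial check on the center pixel counts:
        # noise-free decay maps, so the single-pixel rate test is a valid
        # independent lower bound on the evidence
        base = round(200.0 / 16)
        k_x = round(10.0 * base)
        p_direct = stats.binom.sf(k_x - 1, k_x + base, 0.5)
        assert p_direct < 1e-3

    def test_loop_planted_equally_absent(self):
        planted = {(20, 35): 10.0}
        map_x = make_decay_map(n_bins=80, scale=200.0, planted=planted)
        map_y = make_decay_map(n_bins=80, scale=200.0, planted=planted)
        loops = LoopSet([_loop(20, 35)], RES, "x")
        pw = pairwise_differential(
            loops, map_x, map_y, compute_expected(map_x), compute_expected(map_y)
        )
        assert pw.loops == []

    def test_resolution_mismatch_rejected(self):
        map_x = make_decay_map(n_bins=40, resolution=10_000)
        map_y = make_decay_map(n_bins=40, resolution=20_000)
        with pytest.raises(ValueError):
            pairwise_differential(
                LoopSet([], 10_000), map_x, map_y, None, None
            )


class TestMatchLoops:
    def test_identical_coordinates_matched(self):
        a = [_loop(10, 20)]
        b = [_loop(10, 20)]
        assert match_loops(a, b, RES) == [(0, 0)]

    def test_one_bin_offset_within_tolerance(self):
        a = [_loop(10, 20)]
        b = [_loop(11, 21)]
        assert match_loops(a, b, RES, tol_bins=1) == [(0, 0)]

    def test_two_bin_offset_unmatched(self):
        a = [_loop(10, 20)]
        b = [_loop(12, 20)]
        assert match_loops(a, b, RES, tol_bins=1) == []

    def test_each_loop_used_once_smallest_offset_first(self):
        a = [_loop(10, 20), _loop(11, 20)]
        b = [_loop(10, 20)]
        assert match_loops(a, b, RES) == [(0, 0)]

    def test_different_chromosomes_never_match(self):
        a = [_loop(10, 20, chrom="chr1")]
        b = [_loop(10, 20, chrom="chr2")]
        assert match_loops(a, b, RES) == []


def _pairwise_from_indicator(sample: str, others: list[str],
                             indicator: dict[tuple[int, int], list[bool]]):
    """Build PairwiseDifferential objects from a loop -> [bool per
    comparison] table (loops at fixed far-apart coordinates)."""
    out = []
    for k, other in enumerate(others):
        loops = [_loop(b1, b2, sample_id=sample)
                 for (b1, b2), flags in indicator.items() if flags[k]]
        out.append(PairwiseDifferential(sample, other, loops, 0.001, 1.5))
    return out


class TestGainedLoops:
    def test_threshold_on_comparison_count(self):
        ind = {
            (10, 30): [True, False, False, False],   # 1 of 4 -> excluded
            (50, 80): [True, True, False, False],    # 2 of 4 -> included
            (100, 140): [True, True, True, True],    # 4 of 4 -> included
        }
        pws = _pairwise_from_indicator("s", ["o1", "o2", "o3", "o4"], ind)
        gained = gained_loops_for_sample("s", pws, RES, min_pairwise=2)
        got = {g.loop.bins(RES) for g in gained}
        assert got == {(50, 80), (100, 140)}

    def test_offset_beyond_tolerance_counts_as_distinct(self):
        pws = [
            PairwiseDifferential("s", "o1", [_loop(10, 30)], 0.001, 1.5),
            PairwiseDifferential("s", "o2", [_loop(12, 30)], 0.001, 1.5),
        ]
        assert gained_loops_for_sample("s", pws, RES, tol_bins=1) == []

    def test_one_bin_offset_pools_support(self):
        pws = [
            PairwiseDifferential("s", "o1", [_loop(10, 30)], 0.001, 1.5),
            PairwiseDifferential("s", "o2", [_loop(11, 30)], 0.001, 1.5),
        ]
        gained = gained_loops_for_sample("s", pws, RES, tol_bins=1)
        assert len(gained) == 1
        assert sorted(gained[0].comparisons) == ["s_vs_o1", "s_vs_o2"]

    def test_empty_opposite_group_rejected(self):
        with pytest.raises(ValueError):
            gained_loops_for_sample("s", [], RES)


def _brute_force_consensus(indicator, samples, min_pairwise, min_samples):
    """Exhaustive evaluation of the two-threshold rule on an indicator
    tensor loop -> sample -> [bool per comparison]; loops are far apart so
    coordinate matching is exact."""
    enriched = set()
    for coords, per_sample in indicator.items():
        n_samples = sum(
            1 for s in samples if sum(per_sample[s]) >= min_pairwise
        )
        if n_samples >= min_samples:
            enriched.add(coords)
    return enriched


def _consensus_from_indicator(indicator, samples, others,
                              min_pairwise=2, min_samples=2):
    per_sample_gained = {}
    for s in samples:
        ind_s = {c: per[s] for c, per in indicator.items()}
        pws = _pairwise_from_indicator(s, others, ind_s)
        per_sample_gained[s] = gained_loops_for_sample(
            s, pws, RES, min_pairwise=min_pairwise
        )
    report = subtype_enriched_loops(
        per_sample_gained, RES, group="G",
        min_samples=min_samples, min_pairwise=min_pairwise,
    )
    return {c.loop.bins(RES) for c in report.loops}


class TestConsensusOracle:
    samples = ["n1", "n2", "n3", "n4"]
    others = ["c1", "c2", "c3", "c4"]

    def _random_instance(self, rng, n_loops):
        coords = [(20 + 40 * k, 60 + 40 * k + 30) for k in range(n_loops)]
        return {
            c: {s: list(rng.random(4) < 0.5) for s in self.samples}
            for c in coords
        }

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        indicator = self._random_instance(rng, n_loops=10)
        got = _consensus_from_indicator(indicator, self.samples, self.others)
        expect = _brute_force_consensus(indicator, self.samples, 2, 2)
        assert got == expect

    @pytest.mark.parametrize(
        "min_pairwise,min_samples", [(1, 2), (2, 2), (3, 2), (2, 3), (4, 4)]
    )
    def test_matches_bruteforce_at_other_thresholds(self, min_pairwise, min_samples):
        rng = np.random.default_rng(99)
        indicator = self._random_instance(rng, n_loops=8)
        got = _consensus_from_indicator(
            indicator, self.samples, self.others,
            min_pairwise=min_pairwise, min_samples=min_samples,
        )
        expect = _brute_force_consensus(
            indicator, self.samples, min_pairwise, min_samples
        )
        assert got == expect

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(7)
        indicator = self._random_instance(rng, n_loops=10)
        base = _consensus_from_indicator(indicator, self.samples, self.others,
                                         min_pairwise=2, min_samples=2)
        for mp, ms in [(3, 2), (2, 3), (3, 3)]:
            tighter = _consensus_from_indicator(
                indicator, self.samples, self.others,
                min_pairwise=mp, min_samples=ms,
            )
            assert tighter <= base

    def test_group_relabeling_symmetry(self):
        rng = np.random.default_rng(13)
        ind_a = self._random_instance(rng, n_loops=6)
        ind_b = self._random_instance(rng, n_loops=6)
        a_first = (
            _consensus_from_indicator(ind_a, self.samples, self.others),
            _consensus_from_indicator(ind_b, self.samples, self.others),
        )
        b_first = (
            _consensus_from_indicator(ind_b, self.samples, self.others),
            _consensus_from_indicator(ind_a, self.samples, self.others),
        )
        assert a_first == (b_first[1], b_first[0])


class TestSubtypeConsensus:
    def test_loop_in_two_samples_enriched(self):
        g = {
            "n1": [GainedLoop(_loop(10, 30, sample_id="n1"), ["n1_vs_c1", "n1_vs_c2"])],
            "n2": [GainedLoop(_loop(10, 30, sample_id="n2"), ["n2_vs_c1", "n2_vs_c3"])],
        }
        report = subtype_enriched_loops(g, RES, group="N")
        assert len(report) == 1
        assert report.loops[0].support == {
            "n1": ["n1_vs_c1", "n1_vs_c2"],
            "n2": ["n2_vs_c1", "n2_vs_c3"],
        }

    def test_loop_in_one_sample_excluded(self):
        g = {
            "n1": [GainedLoop(_loop(10, 30), ["n1_vs_c1", "n1_vs_c2"])],
            "n2": [],
        }
        assert len(subtype_enriched_loops(g, RES, group="N")) == 0

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            subtype_enriched_loops({"n1": []}, RES, min_samples=2)

    def test_representative_is_most_frequent_coordinates(self):
        g = {
            "n1": [GainedLoop(_loop(10, 30), ["a", "b"])],
            "n2": [GainedLoop(_loop(10, 30), ["c", "d"])],
            "n3": [GainedLoop(_loop(11, 30), ["e", "f"])],
        }
        report = subtype_enriched_loops(g, RES, group="N")
        assert report.loops[0].loop.bins(RES) == (10, 30)
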