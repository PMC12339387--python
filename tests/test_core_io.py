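"""Containers, interval arithmetic and on-disk format round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loopdiff import BinnedContactMap, Genome, GenomicInterval, LoopCall
from loopdiff.core import ExpressionTable
from loopdiff.intervals import IntervalIndex
from loopdiff import io as ldio


@pytest.fixture
def genome():
    return Genome([("chr1", 1_000_000), ("chr2", 500_000)])


class TestGenomicInterval:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 500, 500)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_half_open_adjacent_intervals_do_not_overlap(self):
        a = GenomicInterval("chr1", 0, 1000)
        b = GenomicInterval("chr1", 1000, 2000)
        assert not a.overlaps(b) and not b.overlaps(a)
        assert a.overlaps(GenomicInterval("chr1", 999, 1001))

    def test_genome_validation(self, genome):
        genome.validate(GenomicInterval("chr1", 0, 1_000_000))
        with pytest.raises(ValueError):
            genome.validate(GenomicInterval("chr3", 0, 10))
        with pytest.raises(ValueError):
            genome.validate(GenomicInterval("chr2", 0, 500_001))

    @given(
        s1=st.integers(0, 200), w1=st.integers(1, 50),
        s2=st.integers(0, 200), w2=st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_matches_shared_bp_count(self, s1, w1, s2, w2):
        a = GenomicInterval("c", s1, s1 + w1)
        b = GenomicInterval("c", s2, s2 + w2)
        shared = max(0, min(a.end, b.end) - max(a.start, b.start))
        assert a.overlaps(b) == (shared >= 1)


class TestIntervalIndex:
    @given(
        refs=st.lists(
            st.tuples(st.integers(0, 100), st.integers(1, 20)), max_size=15
        ),
        queries=st.lists(
            st.tuples(st.integers(0, 100), st.integers(1, 20)),
            min_size=1, max_size=10,
        ),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_overlap(self, refs, queries):
        ref_ivs = [GenomicInterval("c", s, s + w) for s, w in refs]
        idx = IntervalIndex(ref_ivs)
        qs = np.array([s for s, _ in queries])
        qe = np.array([s + w for s, w in queries])
        got = idx.any_overlap("c", qs, qe)
        for k, (s, w) in enumerate(queries):
            q = GenomicInterval("c", s, s + w)
            assert got[k] == any(q.overlaps(r) for r in ref_ivs)


class TestContactMapContainer:
    def test_pixels_stored_upper_triangle(self, genome):
        cmap = BinnedContactMap(
            genome, 10_000,
            {"chr1": (np.array([2]), np.array([1]), np.array([3.0]))},
        )
        i, j, v = cmap.pixels["chr1"]
        assert (i[0], j[0], v[0]) == (1, 2, 3.0)

    def test_duplicate_keys_summed(self, genome):
        cmap = BinnedContactMap(
            genome, 10_000,
            {"chr1": (np.array([1, 2]), np.array([2, 1]), np.array([3.0, 4.0]))},
        )
        assert cmap.pixels["chr1"][2].tolist() == [7.0]

    def test_negative_values_rejected(self, genome):
        with pytest.raises(ValueError):
            BinnedContactMap(
                genome, 10_000,
                {"chr1": (np.array([0]), np.array([1]), np.array([-1.0]))},
            )

    def test_marginals_count_diagonal_once(self, genome):
        cmap = BinnedContactMap(
            genome, 10_000,
            {"chr1": (np.array([0, 0]), np.array([0, 1]), np.array([5.0, 2.0]))},
        )
        m = cmap.marginals("chr1")
        assert m[0] == 7.0 and m[1] == 2.0


class TestContactMapIO:
    def test_round_trip_identity(self, genome, tmp_path):
        rng = np.random.default_rng(0)
        i = rng.integers(0, 50, 30)
        j = i + rng.integers(0, 40, 30)
        cmap = BinnedContactMap(
            genome, 10_000, {"chr1": (i, j, rng.poisson(5.0, 30) + 1.0)}
        )
        p = tmp_path / "m.coo.tsv"
        ldio.write_contact_map(cmap, p)
        back = ldio.read_contact_map(p, genome)
        assert back == cmap

    def test_swapped_coordinates_normalized(self, genome, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("#resolution=10000\n#balanced=false\nchr1\t20000\t10000\t3.0\n")
        cmap = ldio.read_contact_map(p, genome)
        i, j, v = cmap.pixels["chr1"]
        assert (i[0], j[0], v[0]) == (1, 2, 3.0)

    def test_unknown_chromosome_rejected(self, genome, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("#resolution=10000\nchrX\t0\t10000\t1.0\n")
        with pytest.raises(ldio.FormatError):
            ldio.read_contact_map(p, genome)

    def test_off_grid_coordinate_rejected(self, genome, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("#resolution=10000\nchr1\t5000\t10000\t1.0\n")
        with pytest.raises(ldio.FormatError):
            ldio.read_contact_map(p, genome)


class TestBedpeIO:
    def test_round_trip_and_anchor_ordering(self, tmp_path):
        loops = [
            LoopCall(
                GenomicInterval("chr1", 10_000, 20_000),
                GenomicInterval("chr1", 500_000, 510_000),
                observed=4.5, expected_local=1.2, p_value=1e-4, q_value=1e-3,
            )
        ]
        p = tmp_path / "loops.bedpe"
        ldio.write_bedpe(loops, p)
        back = ldio.read_bedpe(p)
        assert len(back) == 1
        assert back[0].anchor1.start == 10_000
        assert back[0].observed == pytest.approx(4.5)
        assert back[0].q_value == pytest.approx(1e-3)

    def test_anchor2_upstream_swapped_on_load(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t500000\t510000\tchr1\t10000\t20000\t.\t.\t.\t.\n")
        (lp,) = ldio.read_bedpe(p)
        assert lp.anchor1.start == 10_000 and lp.anchor2.start == 500_000

    def test_trans_pair_strict_flag(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t0\t10000\tchr2\t0\t10000\t.\t.\t.\t.\n")
        assert ldio.read_bedpe(p) == []
        with pytest.raises(ldio.FormatError):
            ldio.read_bedpe(p, strict_cis=True)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t0\t10000\tchr1\tnotanint\t20000\t.\t.\t.\t.\n")
        with pytest.raises(ldio.FormatError, match=":1"):
            ldio.read_bedpe(p)


class TestIntervalIO:
    def test_bed_and_bedgraph_values(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t1000\nchr1\t0\t100000\t0.41\n")
        ivs = ldio.read_intervals(p)
        assert ivs[0].value is None
        assert ivs[1].value == pytest.approx(0.41)

    def test_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t500\t500\n")
        with pytest.raises(ldio.FormatError):
            ldio.read_intervals(p)

    def test_interval_round_trip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 1000),
            GenomicInterval("chr2", 5, 50, value=1.5),
        ]
        p = tmp_path / "x.bed"
        ldio.write_intervals(ivs, p)
        back = ldio.read_intervals(p)
        assert [(v.chrom, v.start, v.end, v.value) for v in back] == [
            ("chr1", 0, 1000, None),
            ("chr2", 5, 50, 1.5),
        ]


class TestExpressionIO:
    def test_round_trip_with_groups(self, tmp_path):
        values = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        table = ExpressionTable(values, {"s1": "A", "s2": "B"})
        vp, lp = tmp_path / "expr.tsv", tmp_path / "labels.tsv"
        ldio.write_expression(table, vp, lp)
        back = ldio.read_expression(vp, lp)
        pd.testing.assert_frame_equal(back.values, values)
        assert back.groups == {"s1": "A", "s2": "B"}

    def test_missing_group_label_rejected(self):
        values = pd.DataFrame([[1.0]], index=["g"], columns=["s1"])
        with pytest.raises(ValueError):
            ExpressionTable(values, {})
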