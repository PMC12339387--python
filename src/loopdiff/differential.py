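"""Pairwise differential loops and the two-level subtype consensus.

The procedure mirrors the study design: every sample of one group is
compared to every sample of the other group independently; loops
differential at FDR 0.001 in at least ``min_pairwise`` (default 2) of a
sample's pairwise comparisons are that sample's gained loops; loops gained
in at least ``min_samples`` (default 2) samples of a group are the group's
subtype-enriched loops. Loop identity across samples/comparisons allows a
one-bin offset on each anchor by default.

The pairwise differential test is a conditional two-sample Poisson rate
comparison: given raw-equivalent counts k_x, k_y at the matched pixel and
local-background rates b_x, b_y, under H0 of equal O/E rates
k_x | (k_x + k_y) ~ Binomial(k_x + k_y, b_x / (b_x + b_y)); the one-sided
upper tail is the p-value, BH-adjusted per comparison, with an additional
O/E ratio floor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .balance import ExpectedProfile
from .calling import PixelStatsEngine
from .core import BinnedContactMap, LoopCall, LoopSet

__all__ = [
    "PairwiseDifferential",
    "GainedLoop",
    "ConsensusLoop",
    "ConsensusLoopReport",
    "pairwise_differential",
    "match_loops",
    "gained_loops_for_sample",
    "subtype_enriched_loops",
]


@dataclass
class PairwiseDifferential:
    """Loops enriched in sample_x relative to sample_y (x coordinates)."""

    sample_x: str
    sample_y: str
    loops: list[LoopCall]
    fdr_diff: float
    min_ratio: float

    @property
    def tag(self) -> str:
        return f"{self.sample_x}_vs_{self.sample_y}"


@dataclass
class GainedLoop:
    """A loop gained by one sample, with its supporting comparisons."""

    loop: LoopCall
    comparisons: list[str]


@dataclass
class ConsensusLoop:
    loop: LoopCall
    # sample -> supporting pairwise comparison tags
    support: dict[str, list[str]]


@dataclass
class ConsensusLoopReport:
    """Subtype-enriched loops with full provenance."""

    group: str
    loops: list[ConsensusLoop]
    min_pairwise: int
    min_samples: int
    tol_bins: int

    def __len__(self) -> int:
        return len(self.loops)


# ---------------------------------------------------------------------------
# pairwise differential


def pairwise_differential(
    loops_x: LoopSet,
    map_x: BinnedContactMap,
    map_y: BinnedContactMap,
    expected_x: ExpectedProfile,
    expected_y: ExpectedProfile,
    fdr_diff: float = 0.001,
    min_ratio: float = 1.5,
    call_fdr: float = 0.05,
    match_window: int = 1,
    agg_window: int = 1,
    sample_x: Optional[str] = None,
    sample_y: Optional[str] = None,
) -> PairwiseDifferential:
    """Loops of sample x significantly stronger than in sample y.

    Each loop called in x (q <= ``call_fdr``; loops without a q, e.g. from
    external BEDPE, are all tested) is matched to the best pixel within
    ``match_window`` bins in y (by O/E, giving y the benefit of the doubt)
    and tested one-sided toward x. The rate test aggregates raw counts
    over a (2*agg_window+1)^2 window around the matched pixel in both
    maps, so the full blob evidence of a loop enters the conditional
    binomial; ``agg_window=0`` tests the single pixel.
    """
    if map_x.resolution != map_y.resolution:
        raise ValueError("contact maps have different resolutions")
    res = map_x.resolution
    sample_x = sample_x or loops_x.sample_id or "x"
    sample_y = sample_y or "y"
    eng_x = PixelStatsEngine(map_x, expected_x)
    eng_y = PixelStatsEngine(map_y, expected_y)

    tested: list[LoopCall] = []
    pvals: list[float] = []
    ratios: list[float] = []
    for lp in loops_x:
        if np.isfinite(lp.q_value) and lp.q_value > call_fdr:
            continue
        b1, b2 = lp.bins(res)
        raw_x, raw_bg_x, oe_x = eng_x.window_stats(lp.chrom, b1, b2, agg_window)
        if not np.isfinite(oe_x):
            continue
        # best-matching pixel in y within +-match_window bins, by O/E
        n = map_y.n_bins(lp.chrom)
        best = None
        for d1 in range(-match_window, match_window + 1):
            for d2 in range(-match_window, match_window + 1):
                p1, p2 = b1 + d1, b2 + d2
                if not (0 <= p1 < p2 < n):
                    continue
                st = eng_y.window_stats(lp.chrom, p1, p2, agg_window)
                if np.isfinite(st[2]) and (best is None or st[2] > best[2]):
                    best = st
        if best is None:
            continue
        raw_y, raw_bg_y, oe_y = best
        k_x = int(round(raw_x))
        k_y = int(round(raw_y))
        denom = raw_bg_x + raw_bg_y
        if not np.isfinite(denom) or denom <= 0 or k_x + k_y == 0:
            p = 1.0
        else:
            p = float(stats.binom.sf(k_x - 1, k_x + k_y, raw_bg_x / denom))
        tested.append(lp)
        pvals.append(p)
        ratios.append(oe_x / oe_y if oe_y > 0 else np.inf)

    out: list[LoopCall] = []
    if tested:
        q = stats.false_discovery_control(np.array(pvals), method="bh")
        for lp, p, qv, ratio in zip(tested, pvals, q, ratios):
            if qv <= fdr_diff and ratio >= min_ratio:
                out.append(replace(lp, p_value=float(p), q_value=float(qv),
                                   sample_id=sample_x))
    return PairwiseDifferential(sample_x, sample_y, out, fdr_diff, min_ratio)


# ---------------------------------------------------------------------------
# loop matching


def _bins(lp: LoopCall, res: int) -> tuple[int, int]:
    return lp.anchor1.start // res, lp.anchor2.start // res


def match_loops(
    a: Sequence[LoopCall],
    b: Sequence[LoopCall],
    resolution: int,
    tol_bins: int = 1,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of two loop lists.

    A pair is admissible iff both anchors agree within ``tol_bins`` bins
    (same chromosome). Pairs are taken in order of total anchor offset,
    ties broken by the (a, b) coordinates; each loop is used at most once.
    """
    cand = []
    for ia, la in enumerate(a):
        ba = _bins(la, resolution)
        for ib, lb in enumerate(b):
            if la.chrom != lb.chrom:
                continue
            bb = _bins(lb, resolution)
            o1 = abs(ba[0] - bb[0])
            o2 = abs(ba[1] - bb[1])
            if o1 <= tol_bins and o2 <= tol_bins:
                cand.append((o1 + o2, ba, bb, ia, ib))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib))
    return pairs


# ---------------------------------------------------------------------------
# clustering loops across comparisons / samples


def _cluster_loops(
    groups: Sequence[tuple[str, Sequence[LoopCall]]],
    resolution: int,
    tol_bins: int,
) -> list[tuple[LoopCall, dict[str, list[LoopCall]]]]:
    """Cluster loops from several tagged lists by coordinate proximity.

    Each loop joins the existing cluster whose representative matches both
    anchors within ``tol_bins`` (smallest offset, ties to the earliest
    cluster); otherwise it founds a new cluster. Returns (representative,
    members-by-tag); the representative is the most frequent exact
    coordinate pair, ties to the lexicographically smallest.
    """
    clusters: list[dict] = []  # {"coords": Counter, "members": {tag: [loops]}}

    def rep_coords(cl) -> tuple[str, int, int]:
        most = cl["coords"].most_common()
        top = most[0][1]
        return min(c for c, cnt in most if cnt == top)

    for tag, loops in groups:
        for lp in sorted(loops, key=lambda x: (x.chrom, x.anchor1.start, x.anchor2.start)):
            b = _bins(lp, resolution)
            key = (lp.chrom, b[0], b[1])
            best = None
            for k, cl in enumerate(clusters):
                rc = rep_coords(cl)
                if rc[0] != lp.chrom:
                    continue
                o1, o2 = abs(rc[1] - b[0]), abs(rc[2] - b[1])
                if o1 <= tol_bins and o2 <= tol_bins:
                    off = o1 + o2
                    if best is None or off < best[0]:
                        best = (off, k)
            if best is None:
                clusters.append({"coords": Counter([key]), "members": {tag: [lp]}})
            else:
                cl = clusters[best[1]]
                cl["coords"][key] += 1
                cl["members"].setdefault(tag, []).append(lp)

    out = []
    for cl in clusters:
        rc = rep_coords(cl)
        # representative LoopCall: a member at the representative coordinates,
        # else the first member
        rep_loop = None
        for members in cl["members"].values():
            for lp in members:
                b = _bins(lp, resolution)
                if (lp.chrom, b[0], b[1]) == rc:
                    rep_loop = lp
                    break
            if rep_loop:
                break
        if rep_loop is None:
            rep_loop = next(iter(cl["members"].values()))[0]
        out.append((rep_loop, cl["members"]))
    return out


def gained_loops_for_sample(
    sample_id: str,
    pairwise: Sequence[PairwiseDifferential],
    resolution: int,
    min_pairwise: int = 2,
    tol_bins: int = 1,
) -> list[GainedLoop]:
    """Loops differential in >= ``min_pairwise`` of this sample's pairwise
    comparisons against the opposite group."""
    if not pairwise:
        raise ValueError("no pairwise comparisons for sample (empty opposite group)")
    tagged = [(pw.tag, pw.loops) for pw in pairwise]
    gained = []
    for rep, members in _cluster_loops(tagged, resolution, tol_bins):
        tags = sorted(members)
        if len(tags) >= min_pairwise:
            gained.append(GainedLoop(replace(rep, sample_id=sample_id), tags))
    gained.sort(key=lambda g: (g.loop.chrom, g.loop.anchor1.start, g.loop.anchor2.start))
    return gained


def subtype_enriched_loops(
    per_sample_gained: Mapping[str, Sequence[GainedLoop]],
    resolution: int,
    group: str = "",
    min_samples: int = 2,
    min_pairwise: int = 2,
    tol_bins: int = 1,
) -> ConsensusLoopReport:
    """Group-level consensus: loops gained in >= ``min_samples`` samples.

    Provenance records, per consensus loop, which samples supported it and
    through which pairwise comparisons.
    """
    if len(per_sample_gained) < max(min_samples, 2):
        raise ValueError(
            f"group has {len(per_sample_gained)} samples; "
            f"min_samples={min_samples} is unreachable"
        )
    tagged = []
    comparisons_of: dict[tuple[str, str, int, int], list[str]] = {}
    for sample in sorted(per_sample_gained):
        loops = [g.loop for g in per_sample_gained[sample]]
        tagged.append((sample, loops))
        for g in per_sample_gained[sample]:
            b = _bins(g.loop, resolution)
            comparisons_of[(sample, g.loop.chrom, b[0], b[1])] = list(g.comparisons)
    report_loops = []
    for rep, members in _cluster_loops(tagged, resolution, tol_bins):
        if len(members) < min_samples:
            continue
        support = {}
        for sample, loops in sorted(members.items()):
            tags: list[str] = []
            for lp in loops:
                b = _bins(lp, resolution)
                tags.extend(comparisons_of.get((sample, lp.chrom, b[0], b[1]), []))
            support[sample] = sorted(set(tags))
        report_loops.append(ConsensusLoop(rep, support))
    report_loops.sort(
        key=lambda c: (c.loop.chrom, c.loop.anchor1.start, c.loop.anchor2.start)
    )
    return ConsensusLoopReport(
        group=group,
        loops=report_loops,
        min_pairwise=min_pairwise,
        min_samples=min_samples,
        tol_bins=tol_bins,
    )
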