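"""Loop-anchor annotation: CRE overlap with a permutation null, loop-gene
linking with expression integration, and TF-anchored loop filtering.

The CRE enrichment statistic is the fraction of loops with either anchor
overlapping (>= 1 bp) the CRE set; the null replaces every anchor with a
uniformly placed interval of identical width on the same chromosome (loop
pairing preserved) and the empirical p-value uses the add-one estimator
p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable, Genome, GenomicInterval, LoopCall
from .differential import match_loops
from .intervals import IntervalIndex

__all__ = [
    "EnrichmentResult",
    "anchor_cre_overlap",
    "permutation_enrichment",
    "link_genes",
    "differential_expression",
    "annotate_tf_anchored",
]


@dataclass
class EnrichmentResult:
    observed_fraction: float
    null_fractions: np.ndarray
    p_empirical: float
    seed: int
    statistic: str = "loops"

    @property
    def n_perm(self) -> int:
        return len(self.null_fractions)


def _anchor_arrays(loops: Sequence[LoopCall]):
    chroms = np.array([a.chrom for lp in loops for a in (lp.anchor1, lp.anchor2)])
    starts = np.array([a.start for lp in loops for a in (lp.anchor1, lp.anchor2)],
                      dtype=np.int64)
    ends = np.array([a.end for lp in loops for a in (lp.anchor1, lp.anchor2)],
                    dtype=np.int64)
    return chroms, starts, ends


def _anchor_hits(index: IntervalIndex, chroms, starts, ends) -> np.ndarray:
    hits = np.zeros(len(starts), dtype=bool)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        hits[sel] = index.any_overlap(chrom, starts[sel], ends[sel])
    return hits


def _fraction(hits: np.ndarray, statistic: str) -> float:
    if statistic == "anchors":
        return float(hits.mean())
    return float(hits.reshape(-1, 2).any(axis=1).mean())


def anchor_cre_overlap(
    loops: Sequence[LoopCall],
    cres: Sequence[GenomicInterval],
    statistic: str = "loops",
) -> float:
    """Fraction of loops with either anchor overlapping >= 1 CRE
    (``statistic='anchors'``: fraction of individual anchors instead)."""
    if not loops:
        raise ValueError("empty loop list")
    index = IntervalIndex(cres)
    hits = _anchor_hits(index, *_anchor_arrays(loops))
    return _fraction(hits, statistic)


def permutation_enrichment(
    loops: Sequence[LoopCall],
    cres: Sequence[GenomicInterval],
    genome: Genome,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "loops",
    mappable: Optional[Mapping[str, np.ndarray]] = None,
    resolution: Optional[int] = None,
) -> EnrichmentResult:
    """One-sided permutation test of anchor-CRE overlap.

    Every permutation resamples each anchor to a uniform start on its own
    chromosome, keeping its width and the loop pairing. When ``mappable``
    (per-chromosome bin indicator at ``resolution``) is given, resampled
    anchors are restricted to mappable bins.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not loops:
        raise ValueError("empty loop list")
    index = IntervalIndex(cres)
    chroms, starts, ends = _anchor_arrays(loops)
    widths = ends - starts
    observed = _fraction(_anchor_hits(index, chroms, starts, ends), statistic)

    rng = np.random.default_rng(seed)
    n_anchor = len(starts)
    null_hits = np.zeros((n_perm, n_anchor), dtype=bool)
    for chrom in np.unique(chroms):
        sel = np.nonzero(chroms == chrom)[0]
        L = genome.length(str(chrom))
        w = widths[sel]
        if (w > L).any():
            raise ValueError(f"anchor wider than chromosome {chrom}")
        if mappable is not None and resolution is not None:
            ok_bins = np.nonzero(mappable[str(chrom)])[0]
            if len(ok_bins) == 0:
                raise ValueError(f"no mappable bins on {chrom}")
            pick = rng.integers(0, len(ok_bins), size=(n_perm, len(sel)))
            new_starts = ok_bins[pick] * resolution
            new_starts = np.minimum(new_starts, L - w[None, :])
        else:
            new_starts = rng.integers(0, L - w[None, :] + 1, size=(n_perm, len(sel)))
        new_ends = new_starts + w[None, :]
        flat_hits = index.any_overlap(
            str(chrom), new_starts.ravel(), new_ends.ravel()
        ).reshape(n_perm, len(sel))
        null_hits[:, sel] = flat_hits
    if statistic == "anchors":
        null = null_hits.mean(axis=1)
    else:
        null = null_hits.reshape(n_perm, -1, 2).any(axis=2).mean(axis=1)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return EnrichmentResult(observed, null, float(p), seed, statistic)


# ---------------------------------------------------------------------------
# gene linking


def link_genes(
    loops: Sequence[LoopCall],
    genes: Sequence[GenomicInterval],
    flank: int = 3000,
    tss_only: bool = False,
) -> pd.DataFrame:
    """Genes within ``flank`` bp of any loop anchor.

    A gene is linked iff its body (or TSS when ``tss_only``) extended by
    ``flank`` on both sides intersects any anchor. Returns one row per
    linked gene with the supporting loop indices.
    """
    anchors = [a for lp in loops for a in (lp.anchor1, lp.anchor2)]
    loop_of_anchor = np.repeat(np.arange(len(loops)), 2)
    rows = []
    index = IntervalIndex(anchors)
    # per-gene supporting loops need explicit per-anchor checks; the index
    # handles the fast any-overlap rejection first
    for gene in genes:
        if tss_only:
            tss = gene.start if gene.strand != "-" else gene.end - 1
            query = GenomicInterval(gene.chrom, max(0, tss - flank),
                                    tss + flank + 1)
        else:
            query = gene.expanded(flank)
        if not index.overlaps_interval(query):
            continue
        support = sorted(
            {
                int(loop_of_anchor[k])
                for k, a in enumerate(anchors)
                if a.overlaps(query)
            }
        )
        rows.append({"gene": gene.name, "chrom": gene.chrom,
                     "start": gene.start, "end": gene.end,
                     "n_loops": len(support), "loops": support})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "n_loops", "loops"])


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    expr: ExpressionTable,
    group_a: str,
    group_b: str,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    eps: float = 0.1,
) -> pd.DataFrame:
    """Per-gene two-sided t test on FPKM between two sample groups.

    log2FC = log2((mean_A + eps) / (mean_B + eps)); a gene is significant
    iff p < ``p_thresh`` and |log2FC| >= ``lfc_thresh``. Genes with
    identical values in both groups get p = 1.
    """
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 samples per group")
    a = expr.values[sa].values
    b = expr.values[sb].values
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    zero_var = np.isnan(p)
    p = np.where(zero_var & (mean_a == mean_b), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)  # zero variance, different means
    sig = (p < p_thresh) & (np.abs(log2fc) >= lfc_thresh)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "significant": sig,
        },
        index=expr.genes,
    )


# ---------------------------------------------------------------------------
# TF-anchored loops


def annotate_tf_anchored(
    loops: Sequence[LoopCall],
    required_peaks: Sequence[Sequence[GenomicInterval]],
    exclude_loops: Sequence[LoopCall] = (),
    resolution: Optional[int] = None,
    tol_bins: int = 1,
    mode: str = "any_anchor",
) -> list[LoopCall]:
    """Loops whose anchors carry every required peak set, minus exclusions.

    ``mode='any_anchor'``: each peak set must hit >= 1 anchor (either one).
    ``mode='both_anchors'``: each peak set must hit both anchors. Kept
    loops matching a loop of ``exclude_loops`` within ``tol_bins`` are then
    removed.
    """
    if mode not in ("any_anchor", "both_anchors"):
        raise ValueError(f"unknown mode {mode!r}")
    indices = [IntervalIndex(p) for p in required_peaks]
    kept = []
    for lp in loops:
        ok = True
        for idx in indices:
            h1 = idx.overlaps_interval(lp.anchor1)
            h2 = idx.overlaps_interval(lp.anchor2)
            hit = (h1 or h2) if mode == "any_anchor" else (h1 and h2)
            if not hit:
                ok = False
                break
        if ok:
            kept.append(lp)
    if exclude_loops and kept:
        res = resolution or (kept[0].anchor1.width)
        matched = {ia for ia, _ in match_loops(kept, list(exclude_loops),
                                               res, tol_bins)}
        kept = [lp for k, lp in enumerate(kept) if k not in matched]
    return kept
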