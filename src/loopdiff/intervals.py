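"""Vectorized half-open interval overlap queries.

The overlap primitive used by the CRE-enrichment permutation test and by
gene linking: for each query ``[s, e)``, does any reference interval on the
same chromosome share >= 1 bp? Implemented with a per-chromosome sorted
start array plus a running maximum of ends, so a batch of m queries against
n references costs O((m + n) log n).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import GenomicInterval

__all__ = ["IntervalIndex"]


class IntervalIndex:
    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        buckets: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, rows in buckets.items():
            arr = np.array(rows, dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            starts = arr[order, 0]
            ends_cummax = np.maximum.accumulate(arr[order, 1])
            self._by_chrom[chrom] = (starts, ends_cummax)

    def any_overlap(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean array: query k overlaps >= 1 reference interval.

        Overlap of half-open intervals: some reference with start < end_k
        and end > start_k. References with start < end_k form a sorted
        prefix; the running max of their ends decides the second condition.
        """
        entry = self._by_chrom.get(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if entry is None:
            return np.zeros(starts.shape, dtype=bool)
        ref_starts, ref_end_cummax = entry
        idx = np.searchsorted(ref_starts, ends, side="left")
        hit = idx > 0
        safe = np.maximum(idx, 1) - 1
        hit &= ref_end_cummax[safe] > starts
        return hit

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return bool(
            self.any_overlap(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
        )
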