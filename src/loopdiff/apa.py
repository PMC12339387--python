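"""Aggregate peak analysis: O/E pileups at loop pixels and score contrasts.

Loops are piled up on a window (default 5 x 5 bins, i.e. 50 kb x 50 kb at
10 kb) of observed-over-expected values centered on each loop pixel; the
APA score is the mean of the central 3 x 3 square of the averaged matrix.
Group contrasts of per-sample APA scores use a one-sided two-sample
Student's t test (pooled variance; Welch by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .balance import ExpectedProfile
from .core import BinnedContactMap, LoopCall

__all__ = ["APAPileup", "pileup", "apa_score", "compare_apa_groups"]


@dataclass
class APAPileup:
    window_bins: int
    matrix: np.ndarray  # window x window mean O/E over used loops
    n_used: int
    n_skipped: int

    @property
    def apa_score(self) -> float:
        return apa_score(self)


def pileup(
    cmap: BinnedContactMap,
    expected: ExpectedProfile,
    loops: Sequence[LoopCall],
    window_bins: int = 5,
) -> APAPileup:
    """Element-wise mean O/E submatrix over usable loops.

    A loop is skipped when its window crosses a chromosome edge, touches
    the diagonal (any cell with bin_i >= bin_j) or overlaps a masked bin —
    the conditions under which O/E cells would be undefined.
    """
    if not cmap.balanced:
        raise ValueError("pileup requires a balanced map")
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be a positive odd integer")
    h = window_bins // 2
    res = cmap.resolution
    acc = np.zeros((window_bins, window_bins))
    n_used = 0
    n_skipped = 0
    dense_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for lp in loops:
        chrom = lp.chrom
        if chrom not in dense_cache:
            e = expected.values[chrom]
            dense_cache[chrom] = (
                cmap.to_dense(chrom),
                cmap.bin_mask(chrom),
                e,
            )
        dense, mask, e = dense_cache[chrom]
        n = len(mask)
        b1, b2 = lp.bins(res)
        r0, r1 = b1 - h, b1 + h
        c0, c1 = b2 - h, b2 + h
        if r0 < 0 or c0 < 0 or r1 >= n or c1 >= n:
            n_skipped += 1
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        if r1 >= c0:  # any cell with bin_i >= bin_j
            n_skipped += 1
            continue
        if not (mask[rows].all() and mask[cols].all()):
            n_skipped += 1
            continue
        dd = cols[None, :] - rows[:, None]
        e_cells = e[dd]
        if not (np.isfinite(e_cells).all() and (e_cells > 0).all()):
            n_skipped += 1
            continue
        acc += dense[np.ix_(rows, cols)] / e_cells
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable loops for pileup")
    return APAPileup(window_bins, acc / n_used, n_used, n_skipped)


def apa_score(pile: APAPileup) -> float:
    """Mean of the central 3 x 3 square of the pileup matrix."""
    if pile.window_bins < 3:
        raise ValueError("APA score needs a window of >= 3 bins")
    c = pile.window_bins // 2
    return float(pile.matrix[c - 1 : c + 2, c - 1 : c + 2].mean())


def compare_apa_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: str = "greater",
    welch: bool = False,
) -> float:
    """One-sided two-sample t test p-value on per-sample APA scores.

    ``alternative='greater'`` tests mean(a) > mean(b). When both groups are
    constant and equal the statistic is 0 by convention and p = 0.5.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 APA scores per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.5
        better = a.mean() > b.mean()
        return 0.0 if better == (alternative == "greater") else 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return float(res.pvalue)
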