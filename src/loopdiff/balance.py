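"""Matrix balancing (iterative correction) and distance-expected profiles.

Iterative correction (ICE) equalizes the marginals of the symmetric cis
contact matrix by a per-bin multiplicative bias; the distance-expected
profile e[d] is the mean balanced value over all mappable bin pairs at bin
distance d (absent pixels count as zero), the denominator of every
observed/expected transform downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinnedContactMap

__all__ = ["ExpectedProfile", "ice_balance", "compute_expected", "coarsen"]


@dataclass
class ExpectedProfile:
    """Per-chromosome expected value by bin distance.

    ``values[chrom][d]`` is the mean over mappable pixel pairs at distance
    d, NaN where no mappable pair exists; ``n_pairs[chrom][d]`` counts the
    mappable pairs entering each mean; ``mask`` records the mappable-bin
    indicator used.
    """

    resolution: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    n_pairs: dict[str, np.ndarray] = field(default_factory=dict)
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def at(self, chrom: str, d: int) -> float:
        return float(self.values[chrom][d])


def ice_balance(
    cmap: BinnedContactMap, max_iter: int = 200, tol: float = 1e-5
) -> tuple[BinnedContactMap, dict[str, np.ndarray]]:
    """Iteratively correct a raw map; returns (balanced map, bias vectors).

    Each round divides the pixels by the outer product of the marginal
    correction ``f_i = m_i / mean(m)`` (over mappable bins) and accumulates
    it into the bias, until ``max_i |f_i - 1| < tol`` or ``max_iter``
    rounds. Bins with zero raw marginal are masked: their bias is NaN and
    they are excluded from the mean. The bias is rescaled to mean 1 over
    mappable bins at the end (a fixed scale convention).

    Raw-equivalent counts are recoverable as ``balanced * bias_i * bias_j``.
    """
    if cmap.balanced:
        raise ValueError("map is already balanced; refusing to balance twice")
    if tol <= 0:
        raise ValueError("tol must be positive")
    new_pixels = {}
    biases: dict[str, np.ndarray] = {}
    any_mappable = False
    for chrom in cmap.genome.chroms:
        i, j, v = cmap.pixels[chrom]
        n = cmap.n_bins(chrom)
        w = v.astype(float).copy()
        bias = np.ones(n)
        mappable = cmap.marginals(chrom) > 0
        if mappable.any():
            any_mappable = True
        off = i != j
        for _ in range(max_iter):
            m = np.bincount(i, weights=w, minlength=n)
            m += np.bincount(j[off], weights=w[off], minlength=n)
            if not mappable.any():
                break
            f = m / m[mappable].mean()
            f[~mappable] = 1.0
            if np.abs(f[mappable] - 1.0).max() < tol:
                break
            w /= f[i] * f[j]
            bias *= f
        if mappable.any():
            scale = bias[mappable].mean()
            bias /= scale
            w *= scale * scale
        bias[~mappable] = np.nan
        new_pixels[chrom] = (i.copy(), j.copy(), w)
        biases[chrom] = bias
    if not any_mappable:
        raise ValueError("all bins are empty; nothing to balance")
    balanced = BinnedContactMap(
        cmap.genome, cmap.resolution, new_pixels, balanced=True, bias=biases
    )
    return balanced, biases


def compute_expected(cmap: BinnedContactMap) -> ExpectedProfile:
    """Mean balanced value per bin distance over mappable pairs.

    Absent pixels contribute zero to the numerator but are counted in the
    denominator (sum / n_pairs, not sum / nnz) — required for an unbiased
    O/E on sparse maps. Pixels touching a masked bin cannot exist by
    construction (masked bins have zero marginal).
    """
    if not cmap.balanced:
        raise ValueError("expected profile requires a balanced map")
    prof = ExpectedProfile(resolution=cmap.resolution)
    for chrom in cmap.genome.chroms:
        i, j, v = cmap.pixels[chrom]
        n = cmap.n_bins(chrom)
        mask = cmap.bin_mask(chrom)
        sums = np.bincount(j - i, weights=v, minlength=n)
        m = mask.astype(float)
        # pairs(d) = sum_i mask[i] * mask[i + d]; full autocorrelation
        pairs = np.correlate(m, m, mode="full")[n - 1 :]
        pairs = np.round(pairs).astype(np.int64)
        e = np.full(n, np.nan)
        has = pairs > 0
        e[has] = sums[has] / pairs[has]
        prof.values[chrom] = e
        prof.n_pairs[chrom] = pairs
        prof.mask[chrom] = mask
    return prof


def coarsen(cmap: BinnedContactMap, factor: int) -> BinnedContactMap:
    """Aggregate a raw map to a coarser resolution by pixel summation.

    Used to derive compartment-resolution (e.g. 100 kb) maps from the
    loop-resolution (10 kb) maps, so one simulated cohort serves both
    analyses. Balanced maps must be re-balanced after coarsening, so only
    raw maps are accepted.
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    if cmap.balanced:
        raise ValueError("coarsen raw maps, then balance at the new resolution")
    pixels = {}
    for chrom in cmap.genome.chroms:
        i, j, v = cmap.pixels[chrom]
        pixels[chrom] = (i // factor, j // factor, v)
    return BinnedContactMap(
        cmap.genome, cmap.resolution * factor, pixels, balanced=False
    )
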