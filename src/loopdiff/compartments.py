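"""A/B compartment eigenvector tracks and sample-relatedness clustering.

The classic construction: per chromosome, the O/E matrix over mappable
bins (clipped to tame sparse outliers) is turned into a Pearson
correlation matrix across bin profiles; the leading eigenvector (largest
|eigenvalue|), scaled by sqrt(|eigenvalue|), is the compartment track,
sign-oriented so that it correlates positively with a phasing track
(GC content in real data). Sample relatedness is the Pearson correlation
of eigenvector tracks over the most variable bins, hierarchically
clustered on 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .balance import ExpectedProfile
from .core import BinnedContactMap

logger = logging.getLogger(__name__)

__all__ = [
    "EigenTrack",
    "compartment_eigenvector",
    "variable_bin_correlation",
    "cluster_samples",
]


@dataclass
class EigenTrack:
    """Per-bin leading-eigenvector values at compartment resolution.

    Masked/undefined bins are NaN. ``degenerate`` lists chromosomes whose
    correlation matrix had no usable structure (E1 returned all-zero).
    """

    sample_id: Optional[str]
    resolution: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    phasing_oriented: bool = False
    degenerate: list[str] = field(default_factory=list)


def compartment_eigenvector(
    cmap: BinnedContactMap,
    expected: ExpectedProfile,
    phasing: Mapping[str, np.ndarray],
    clip: tuple[float, float] = (0.01, 100.0),
    use_corr: bool = True,
    min_bins: int = 10,
    sample_id: Optional[str] = None,
) -> EigenTrack:
    """Leading eigenvector of the O/E (Pearson-correlation) matrix.

    ``use_corr=False`` decomposes O/E - 1 directly instead (some tools'
    convention). Chromosomes with fewer than ``min_bins`` mappable bins are
    skipped with a warning.
    """
    if not cmap.balanced:
        raise ValueError("compartment eigenvector requires a balanced map")
    track = EigenTrack(sample_id=sample_id, resolution=cmap.resolution)
    for chrom in cmap.genome.chroms:
        n = cmap.n_bins(chrom)
        out = np.full(n, np.nan)
        mask = cmap.bin_mask(chrom)
        e = expected.values[chrom]
        idx = np.nonzero(mask)[0]
        if len(idx) < min_bins:
            logger.warning("%s: only %d mappable bins, skipped", chrom, len(idx))
            track.values[chrom] = out
            continue
        dense = cmap.to_dense(chrom)[np.ix_(idx, idx)]
        dd = np.abs(idx[None, :] - idx[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = dense / e[dd]
        oe[~np.isfinite(oe)] = 1.0
        oe = np.clip(oe, clip[0], clip[1])
        if use_corr:
            sd = oe.std(axis=0)
            if np.any(sd == 0):
                degenerate = (sd == 0).all()
            else:
                degenerate = False
            if degenerate:
                track.degenerate.append(chrom)
                track.values[chrom] = np.where(mask, 0.0, np.nan)
                continue
            keep = sd > 0
            sub = oe[np.ix_(keep, keep)]
            mat = np.corrcoef(sub)
            sub_idx = idx[keep]
        else:
            mat = oe - 1.0
            sub_idx = idx
        if not np.isfinite(mat).all():
            track.degenerate.append(chrom)
            track.values[chrom] = np.where(mask, 0.0, np.nan)
            continue
        evals, evecs = np.linalg.eigh(mat)
        k = int(np.argmax(np.abs(evals)))
        e1 = evecs[:, k] * np.sqrt(abs(evals[k]))
        ph = np.asarray(phasing[chrom], dtype=float)[sub_idx]
        ok = np.isfinite(ph)
        if ok.sum() >= 2 and np.std(e1[ok]) > 0 and np.std(ph[ok]) > 0:
            r = np.corrcoef(e1[ok], ph[ok])[0, 1]
            if r < 0:
                e1 = -e1
        out[sub_idx] = e1
        track.values[chrom] = out
    track.phasing_oriented = True
    return track


def variable_bin_correlation(
    tracks: Sequence[EigenTrack], top_frac: float = 0.25
) -> pd.DataFrame:
    """Pairwise Pearson correlation of eigenvector tracks over the top
    ``top_frac`` most variable bins.

    Only bins defined and nonzero in every track are eligible (exact-zero
    values mark degenerate chromosomes and are treated as undefined); bins
    are ranked by across-sample variance.
    """
    if len(tracks) < 2:
        raise ValueError("need >= 2 eigenvector tracks")
    res = tracks[0].resolution
    chroms = list(tracks[0].values)
    for t in tracks[1:]:
        if t.resolution != res or list(t.values) != chroms:
            raise ValueError("tracks must share resolution and chromosomes")
    mat = np.vstack(
        [np.concatenate([t.values[c] for c in chroms]) for t in tracks]
    )
    usable = np.isfinite(mat).all(axis=0) & (mat != 0).all(axis=0)
    if not usable.any():
        raise ValueError("no bins defined and nonzero in all tracks")
    sub = mat[:, usable]
    var = sub.var(axis=0)
    k = max(1, int(np.ceil(top_frac * sub.shape[1])))
    top = np.argsort(-var, kind="stable")[:k]
    corr = np.corrcoef(sub[:, top])
    ids = [t.sample_id or f"S{i}" for i, t in enumerate(tracks)]
    return pd.DataFrame(corr, index=ids, columns=ids)


def cluster_samples(
    corr: pd.DataFrame, method: str = "average", k: int = 2
) -> tuple[np.ndarray, dict[str, int]]:
    """Hierarchical clustering of samples on distance 1 - r.

    Samples are processed in lexicographic id order so ties resolve
    deterministically. Returns the scipy linkage matrix (rows follow the
    sorted sample order) and a flat k-cluster labeling.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(corr.values), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if not np.allclose(corr.values, corr.values.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    order = sorted(corr.index)
    c = corr.loc[order, order].values
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, dict(zip(order, (int(x) for x in flat)))
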