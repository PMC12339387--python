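"""Core genomic containers shared by every stage of the pipeline.

Coordinates are 0-based, half-open (BED convention) throughout: an interval
``[start, end)`` covers ``end - start`` bp, and ``[a, b)`` / ``[b, c)`` do not
overlap. Contact maps store only the cis upper triangle (``bin_i <= bin_j``)
at a fixed resolution; symmetry is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Genome",
    "BinnedContactMap",
    "ExpressionTable",
    "LoopCall",
    "LoopSet",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``name``, ``value`` and ``strand`` are optional annotations (BED name
    column, bedGraph value, gene strand); they never affect interval
    arithmetic.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    value: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, flank: int) -> "GenomicInterval":
        """Interval extended by ``flank`` bp on both sides (floored at 0)."""
        return replace(self, start=max(0, self.start - flank), end=self.end + flank)


class Genome:
    """An ordered set of chromosomes with lengths in bp."""

    def __init__(self, chromsizes: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in chromsizes:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._names.append(name)
            self._lengths[name] = length

    @property
    def chroms(self) -> list[str]:
        return list(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return list(self) == list(other)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self._lengths[chrom] // resolution)  # ceil division

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._lengths[iv.chrom]}"
            )


class BinnedContactMap:
    """Cis contact values on a fixed-resolution bin grid.

    Pixels are stored per chromosome as parallel ``(bin_i, bin_j, value)``
    arrays with ``bin_i <= bin_j`` (upper triangle); the matrix is symmetric
    by construction. ``bias`` holds the per-bin multiplicative factors from
    iterative correction when the map has been balanced (NaN for masked
    bins), so raw-equivalent counts can be reconstructed as
    ``value * bias[i] * bias[j]``.
    """

    def __init__(
        self,
        genome: Genome,
        resolution: int,
        pixels: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        balanced: bool = False,
        bias: dict[str, np.ndarray] | None = None,
    ):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.genome = genome
        self.resolution = int(resolution)
        self.balanced = bool(balanced)
        self.bias = bias
        self.pixels: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in genome.chroms:
            if pixels and chrom in pixels:
                i, j, v = pixels[chrom]
                self.pixels[chrom] = self._canonical(chrom, i, j, v)
            else:
                empty = np.array([], dtype=np.int64)
                self.pixels[chrom] = (empty, empty.copy(), np.array([], dtype=float))

    def _canonical(
        self, chrom: str, i: np.ndarray, j: np.ndarray, v: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        v = np.asarray(v, dtype=float)
        if not (len(i) == len(j) == len(v)):
            raise ValueError("pixel arrays must have equal length")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        n = self.genome.n_bins(chrom, self.resolution)
        if len(lo) and (lo.min() < 0 or hi.max() >= n):
            raise ValueError(f"bin index out of range for {chrom}")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValueError("pixel values must be finite and non-negative")
        order = np.lexsort((hi, lo))
        lo, hi, v = lo[order], hi[order], v[order]
        # collapse duplicate keys (i, j) by summation
        if len(lo) > 1:
            key_change = np.empty(len(lo), dtype=bool)
            key_change[0] = True
            key_change[1:] = (np.diff(lo) != 0) | (np.diff(hi) != 0)
            if not key_change.all():
                idx = np.cumsum(key_change) - 1
                v = np.bincount(idx, weights=v)
                lo, hi = lo[key_change], hi[key_change]
        return lo, hi, v

    # -- basic accessors ---------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        return self.genome.n_bins(chrom, self.resolution)

    def nnz(self) -> int:
        return sum(len(p[0]) for p in self.pixels.values())

    def total(self) -> float:
        return float(sum(p[2].sum() for p in self.pixels.values()))

    def marginals(self, chrom: str) -> np.ndarray:
        """Row sums of the (symmetric) matrix; diagonal counted once."""
        i, j, v = self.pixels[chrom]
        n = self.n_bins(chrom)
        m = np.bincount(i, weights=v, minlength=n)
        off = i != j
        m += np.bincount(j[off], weights=v[off], minlength=n)
        return m

    def bin_mask(self, chrom: str) -> np.ndarray:
        """Usable-bin indicator: bins with nonzero marginal.

        On a balanced map the mask is taken from the bias vector (bins whose
        bias is defined), so masking survives the balancing transform.
        """
        if self.bias is not None and chrom in self.bias:
            return np.isfinite(self.bias[chrom])
        return self.marginals(chrom) > 0

    def to_dense(self, chrom: str, dtype=float) -> np.ndarray:
        """Full symmetric dense matrix for one chromosome."""
        i, j, v = self.pixels[chrom]
        n = self.n_bins(chrom)
        m = np.zeros((n, n), dtype=dtype)
        m[i, j] = v
        m[j, i] = v
        return m

    def copy(self) -> "BinnedContactMap":
        pix = {c: (i.copy(), j.copy(), v.copy()) for c, (i, j, v) in self.pixels.items()}
        bias = None
        if self.bias is not None:
            bias = {c: b.copy() for c, b in self.bias.items()}
        return BinnedContactMap(self.genome, self.resolution, pix, self.balanced, bias)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinnedContactMap):
            return NotImplemented
        if (
            self.genome != other.genome
            or self.resolution != other.resolution
            or self.balanced != other.balanced
        ):
            return False
        for chrom in self.genome.chroms:
            a, b = self.pixels[chrom], other.pixels[chrom]
            if not all(np.array_equal(x, y) for x, y in zip(a, b)):
                return False
        return True


@dataclass(frozen=True)
class LoopCall:
    """A called chromatin loop: two one-bin anchors on the same chromosome.

    ``observed`` is the balanced contact value at the loop pixel,
    ``expected_local`` the local-background expectation in the same units.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    observed: float = np.nan
    expected_local: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must be on the same chromosome")
        if self.anchor1.start >= self.anchor2.start:
            raise ValueError("anchor1 must be strictly upstream of anchor2")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    def bins(self, resolution: int) -> tuple[int, int]:
        return self.anchor1.start // resolution, self.anchor2.start // resolution

    def span(self) -> int:
        return self.anchor2.start - self.anchor1.start


@dataclass
class LoopSet:
    """A list of loop calls from one sample at one resolution."""

    loops: list[LoopCall]
    resolution: int
    sample_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self) -> Iterator[LoopCall]:
        return iter(self.loops)

    def __getitem__(self, idx: int) -> LoopCall:
        return self.loops[idx]


class ExpressionTable:
    """Gene-by-sample expression (FPKM) with a group label per sample."""

    def __init__(self, values: pd.DataFrame, groups: dict[str, str]):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if (values.values < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in values.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.values = values
        self.groups = {s: groups[s] for s in values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]
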