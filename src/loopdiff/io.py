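"""Readers and writers for the on-disk formats used by the pipeline.

Formats (all plain text, TAB-separated):

* chrom.sizes — ``chrom<TAB>length``.
* Contact map COO dialect — header lines ``#resolution=<int>`` and
  ``#balanced=<true|false>``, then ``chrom<TAB>start1<TAB>start2<TAB>value``
  where start1/start2 are bin start coordinates (multiples of the
  resolution). Only cis pixels are stored; an optional
  ``#bias:<chrom>=v1,v2,...`` header carries the balancing bias vector.
* BEDPE for loops — six mandatory columns, optional named extras
  (``observed``, ``expected_local``, ``p``, ``q``) declared in a ``#``
  header line.
* BED3+ / bedGraph for intervals; a numeric 4th column is attached as the
  interval value, a non-numeric one as its name.
* Expression TSV — genes x samples with a header row; sample groups in a
  two-column ``sample<TAB>group`` file.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    BinnedContactMap,
    ExpressionTable,
    Genome,
    GenomicInterval,
    LoopCall,
    LoopSet,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

BEDPE_EXTRA_COLS = ("observed", "expected_local", "p", "q")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chromsizes(path: PathLike) -> Genome:
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected 'chrom<TAB>length'")
        pairs.append((parts[0], int(parts[1])))
    return Genome(pairs)


def write_chromsizes(genome: Genome, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# contact map COO dialect


def write_contact_map(cmap: BinnedContactMap, path: PathLike) -> None:
    res = cmap.resolution
    with open(path, "w") as fh:
        fh.write(f"#resolution={res}\n")
        fh.write(f"#balanced={'true' if cmap.balanced else 'false'}\n")
        if cmap.bias is not None:
            for chrom, b in cmap.bias.items():
                fh.write(f"#bias:{chrom}=" + ",".join(f"{x:.10g}" for x in b) + "\n")
        for chrom in cmap.genome.chroms:
            i, j, v = cmap.pixels[chrom]
            for bi, bj, val in zip(i, j, v):
                fh.write(f"{chrom}\t{bi * res}\t{bj * res}\t{val:.10g}\n")


def read_contact_map(
    path: PathLike, genome: Genome, resolution: Optional[int] = None
) -> BinnedContactMap:
    """Load a COO-dialect contact map.

    ``resolution``, when given, must match the file header. Pixels are
    normalized to upper-triangle storage (coordinates swapped if needed).
    """
    header_res: Optional[int] = None
    balanced = False
    bias: dict[str, np.ndarray] = {}
    data: dict[str, list[tuple[int, int, float]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:]
            if body.startswith("resolution="):
                header_res = int(body.split("=", 1)[1])
            elif body.startswith("balanced="):
                balanced = body.split("=", 1)[1].strip().lower() == "true"
            elif body.startswith("bias:"):
                chrom, vec = body[5:].split("=", 1)
                bias[chrom] = np.array([float(x) for x in vec.split(",")])
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 columns")
        chrom, s1, s2, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in genome:
            raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        res = header_res if header_res is not None else resolution
        if res is None:
            raise FormatError(f"{path}: no #resolution header and none given")
        if s1 % res or s2 % res:
            raise FormatError(
                f"{path}:{ln}: coordinate not a multiple of resolution {res}"
            )
        data.setdefault(chrom, []).append((s1 // res, s2 // res, val))
    if header_res is None:
        if resolution is None:
            raise FormatError(f"{path}: no #resolution header and none given")
        header_res = resolution
    if resolution is not None and header_res != resolution:
        raise FormatError(
            f"{path}: header resolution {header_res} != requested {resolution}"
        )
    pixels = {}
    for chrom, rows in data.items():
        arr = np.array(rows, dtype=float)
        pixels[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return BinnedContactMap(
        genome, header_res, pixels, balanced=balanced, bias=bias or None
    )


# ---------------------------------------------------------------------------
# BEDPE loops


def write_bedpe(loops: Union[LoopSet, Sequence[LoopCall]], path: PathLike) -> None:
    rows = list(loops)
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\t" + "\t".join(BEDPE_EXTRA_COLS) + "\n"
        )
        for lp in rows:
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{lp.sample_id or '.'}\t.\t.\t.\t"
                f"{lp.observed:.10g}\t{lp.expected_local:.10g}\t"
                f"{lp.p_value:.6g}\t{lp.q_value:.6g}\n"
            )


def read_bedpe(
    path: PathLike, strict_cis: bool = False, sample_id: Optional[str] = None
) -> list[LoopCall]:
    """Read loops from BEDPE; anchors are ordered so anchor1 is upstream.

    Trans pairs (different chromosomes) raise when ``strict_cis`` is set and
    are skipped (with a logged count) otherwise.
    """
    loops: list[LoopCall] = []
    extra_idx: dict[str, int] = {}
    n_trans = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            cols = line[1:].split("\t")
            extra_idx = {c: k for k, c in enumerate(cols) if c in BEDPE_EXTRA_COLS}
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(f"{path}:{ln}: BEDPE needs >= 6 columns")
        try:
            c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
            c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: {err}") from None
        if c1 != c2:
            if strict_cis:
                raise FormatError(f"{path}:{ln}: trans pair {c1}/{c2}")
            n_trans += 1
            continue
        if (s2, e2) < (s1, e1):
            s1, e1, s2, e2 = s2, e2, s1, e1
        def _extra(name: str, default: float = np.nan) -> float:
            k = extra_idx.get(name)
            if k is None or k >= len(parts) or parts[k] in (".", ""):
                return default
            return float(parts[k])
        try:
            loops.append(
                LoopCall(
                    GenomicInterval(c1, s1, e1),
                    GenomicInterval(c2, s2, e2),
                    observed=_extra("observed"),
                    expected_local=_extra("expected_local"),
                    p_value=_extra("p"),
                    q_value=_extra("q"),
                    sample_id=sample_id,
                )
            )
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: {err}") from None
    if n_trans:
        logger.info("%s: skipped %d trans pairs", path, n_trans)
    return loops


# ---------------------------------------------------------------------------
# BED / bedGraph intervals


def read_intervals(path: PathLike) -> list[GenomicInterval]:
    """Read BED3+ or bedGraph. A numeric 4th column becomes the interval
    value (bedGraph), a non-numeric one its name; a 6th column is strand."""
    out: list[GenomicInterval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: {err}") from None
        name = value = strand = None
        if len(parts) >= 4 and parts[3] not in (".", ""):
            try:
                value = float(parts[3])
            except ValueError:
                name = parts[3]
        if len(parts) >= 6 and parts[5] in ("+", "-"):
            strand = parts[5]
        try:
            out.append(GenomicInterval(chrom, start, end, name=name, value=value,
                                       strand=strand))
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: {err}") from None
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.value is not None:
                cols.append(f"{iv.value:.6g}")
            elif iv.name is not None:
                cols.append(iv.name)
                if iv.strand is not None:
                    cols += [".", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_genes(path: PathLike) -> list[GenomicInterval]:
    """Gene annotation: BED-like TSV ``chrom start end gene_id [strand]``."""
    genes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: gene annotation needs 4 columns")
        strand = parts[4] if len(parts) > 4 and parts[4] in ("+", "-") else None
        genes.append(
            GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                            name=parts[3], strand=strand)
        )
    return genes


# ---------------------------------------------------------------------------
# expression / labels


def read_expression(values_path: PathLike, labels_path: PathLike) -> ExpressionTable:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", header=None,
                         names=["sample", "group"], comment="#")
    groups = dict(zip(labels["sample"].astype(str), labels["group"].astype(str)))
    return ExpressionTable(values, groups)


def write_expression(table: ExpressionTable, values_path: PathLike,
                     labels_path: PathLike) -> None:
    table.values.to_csv(values_path, sep="\t")
    with open(labels_path, "w") as fh:
        for sample, group in table.groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# eigenvector tracks (bedGraph)


def write_eigentrack(track, path: PathLike) -> None:
    """Write an EigenTrack as bedGraph; undefined bins are skipped."""
    res = track.resolution
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            for b, x in enumerate(vals):
                if np.isfinite(x):
                    fh.write(f"{chrom}\t{b * res}\t{(b + 1) * res}\t{x:.6g}\n")
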