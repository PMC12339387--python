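"""Synthetic two-group Hi-C cohort with planted loops and matched omics.

The generator emulates the statistical structure the downstream analysis
assumes: ICE-balanceable cis maps with power-law distance decay and Poisson
counts, planted shared and group-specific loops (multiplicative enrichment
``phi`` with a Gaussian spill of ``sigma`` bins), a checkerboard A/B
compartment factor at 100 kb granularity (a fraction of compartment blocks
flips label between groups, giving the groups distinguishable eigenvector
tracks), CRE interval sets concentrated at group-specific anchors, and an
FPKM expression table in which loop-linked genes carry a planted log2
fold-change.

Pixel means follow

    lambda_ij = depth * Z^-1 * (|i - j| + 1)^-alpha * B_ij * C_ij

where ``B_ij`` is the loop boost (peaking at ``phi`` on loop pixels planted
for the sample's group), ``C_ij`` the compartment factor (``strength`` for
same-label bin pairs, its reciprocal otherwise) and ``Z`` normalizes the
total expectation to ``depth``. Counts are independent Poisson draws; the
full cohort is reproducible from ``config.seed`` alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import BinnedContactMap, ExpressionTable, Genome, GenomicInterval
import pandas as pd

__all__ = [
    "CohortSimConfig",
    "TruthLoop",
    "CohortTruth",
    "CohortSample",
    "make_truth",
    "simulate_contact_map",
    "simulate_cohort",
    "make_gene_annotation",
    "simulate_expression_and_cres",
    "make_phasing_track",
]

# named substreams of config.seed (spawn keys); samples use 100 + index
_STREAM_TRUTH = 0
_STREAM_GENES = 1
_STREAM_EXPR = 2
_STREAM_CRES = 3
_STREAM_PHASING = 4
_STREAM_SAMPLES = 100


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def derive_sample_seed(seed: int, sample_index: int) -> int:
    """Deterministic per-sample integer seed (< 2**31) from the root seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAM_SAMPLES + sample_index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class CohortSimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the simulated study design: a 4 vs 4 two-group cohort
    on one 50 Mb chromosome at 10 kb, sequencing depth 1e7 cis pairs per
    sample, 40 shared plus 30 + 30 group-specific loops of 8-fold
    enrichment, and loop-linked genes shifted by 2 log2 units.
    """

    seed: int = 0
    n_group_a: int = 4
    n_group_b: int = 4
    chrom_name: str = "chrS"
    chrom_length: int = 50_000_000
    resolution: int = 10_000
    decay_exponent: float = 1.0  # alpha of the power-law distance decay
    depth: float = 1e7  # expected total cis pairs per sample
    loop_enrichment: float = 8.0  # phi, multiplicative at loop pixels
    loop_spill: float = 0.75  # sigma, bins of Gaussian spread
    n_shared: int = 40
    n_a_specific: int = 30
    n_b_specific: int = 30
    min_loop_span: int = 200_000
    max_loop_span: int = 1_500_000
    compartment_block_size: int = 2_500_000
    compartment_resolution: int = 100_000
    compartment_strength: float = 1.5  # O/E contrast (same vs cross label)
    compartment_flip_frac: float = 0.25  # blocks whose label flips in group B
    expr_effect: float = 2.0  # log2 FC planted on loop-linked genes
    expr_noise_sd: float = 0.25  # SD of i.i.d. log2 expression noise
    cre_signal_frac: float = 0.5  # CREs centered on group-specific anchors
    n_cres: int = 300
    cre_width: int = 2_000
    n_genes: int = 600
    gene_width: int = 2_000
    gene_link_flank: int = 3_000
    phasing_noise_sd: float = 0.2
    loop_clearance_bins: int = 12  # min Chebyshev pixel distance between loops
    group_a: str = "A"
    group_b: str = "B"

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b, self.n_shared,
               self.n_a_specific, self.n_b_specific) < 0:
            raise ValueError("counts must be >= 0")
        if self.loop_enrichment < 1:
            raise ValueError("loop_enrichment must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 <= self.cre_signal_frac <= 1):
            raise ValueError("cre_signal_frac must be in [0, 1]")
        if self.min_loop_span > self.max_loop_span:
            raise ValueError("min_loop_span > max_loop_span")
        if self.compartment_resolution % self.resolution:
            raise ValueError("compartment_resolution must be a multiple of resolution")

    @property
    def genome(self) -> Genome:
        return Genome([(self.chrom_name, self.chrom_length)])

    def sample_ids(self) -> list[tuple[str, str]]:
        """Ordered (sample_id, group) pairs: A1..An then B1..Bm."""
        ids = [(f"{self.group_a}{k + 1}", self.group_a)
               for k in range(self.n_group_a)]
        ids += [(f"{self.group_b}{k + 1}", self.group_b)
                for k in range(self.n_group_b)]
        return ids


@dataclass(frozen=True)
class TruthLoop:
    loop_id: str
    chrom: str
    bin1: int
    bin2: int
    klass: str  # "shared" | "A_specific" | "B_specific"

    def anchors(self, resolution: int, chrom_length: int) -> tuple[GenomicInterval, GenomicInterval]:
        def iv(b: int) -> GenomicInterval:
            return GenomicInterval(
                self.chrom, b * resolution, min((b + 1) * resolution, chrom_length)
            )
        return iv(self.bin1), iv(self.bin2)


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort (the acceptance oracle)."""

    loops: list[TruthLoop]
    # per-group +1/-1 compartment label per compartment-resolution bin
    compartment_labels: dict[str, np.ndarray]
    # filled by simulate_expression_and_cres: gene id -> (class, loop ids)
    gene_links: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def loops_of(self, klass: str) -> list[TruthLoop]:
        return [lp for lp in self.loops if lp.klass == klass]


@dataclass
class CohortSample:
    sample_id: str
    group: str
    cmap: BinnedContactMap


# ---------------------------------------------------------------------------
# truth construction


def _compartment_labels(config: CohortSimConfig) -> dict[str, np.ndarray]:
    n_comp = -(-config.chrom_length // config.compartment_resolution)
    bins_per_block = max(1, config.compartment_block_size // config.compartment_resolution)
    block_of = np.arange(n_comp) // bins_per_block
    labels_a = np.where(block_of % 2 == 0, 1, -1).astype(np.int8)
    n_blocks = int(block_of.max()) + 1
    rng = _rng(config.seed, _STREAM_TRUTH)
    n_flip = int(round(config.compartment_flip_frac * n_blocks))
    flip_blocks = rng.choice(n_blocks, size=n_flip, replace=False) if n_flip else []
    labels_b = labels_a.copy()
    for blk in flip_blocks:
        labels_b[block_of == blk] *= -1
    return {config.group_a: labels_a, config.group_b: labels_b}


def make_truth(config: CohortSimConfig) -> CohortTruth:
    """Place planted loops without collision and fix compartment labels.

    Loops are rejected-sampled so that any two planted pixels are more than
    ``loop_clearance_bins`` apart in Chebyshev distance (clear of each
    other's APA window and local background), clear of chromosome edges,
    and within the configured span band. Shared loops are additionally
    constrained to anchor pairs whose compartment-label parity (same vs
    opposite label) is identical in both groups: a loop whose anchors fall
    in a block that flips label between groups would carry a group-level
    compartment contrast on top of the loop boost and would not actually be
    shared in strength.
    """
    labels = _compartment_labels(config)
    rng = _rng(config.seed, _STREAM_TRUTH)
    res = config.resolution
    n = -(-config.chrom_length // res)
    lo_span = max(1, config.min_loop_span // res)
    hi_span = max(lo_span, config.max_loop_span // res)
    edge = config.loop_clearance_bins
    classes = (
        ["shared"] * config.n_shared
        + ["A_specific"] * config.n_a_specific
        + ["B_specific"] * config.n_b_specific
    )
    if n - 1 - 2 * edge <= lo_span and classes:
        raise ValueError("chromosome too short to place the requested loops")
    ratio = config.compartment_resolution // config.resolution
    lab_a = labels[config.group_a]
    lab_b = labels[config.group_b]

    def parity_concordant(b1: int, b2: int) -> bool:
        c1, c2 = b1 // ratio, b2 // ratio
        return (lab_a[c1] == lab_a[c2]) == (lab_b[c1] == lab_b[c2])

    placed: list[tuple[int, int]] = []
    loops: list[TruthLoop] = []
    max_tries = 20_000
    for k, klass in enumerate(classes):
        for _ in range(max_tries):
            span = int(rng.integers(lo_span, hi_span + 1))
            b1 = int(rng.integers(edge, n - span - edge))
            b2 = b1 + span
            if klass == "shared" and not parity_concordant(b1, b2):
                continue
            if all(max(abs(b1 - p1), abs(b2 - p2)) > config.loop_clearance_bins
                   for p1, p2 in placed):
                placed.append((b1, b2))
                loops.append(TruthLoop(f"L{k:04d}", config.chrom_name, b1, b2, klass))
                break
        else:
            raise ValueError(
                "chromosome too short to place the requested loops without collision"
            )
    return CohortTruth(loops=loops, compartment_labels=labels)


# ---------------------------------------------------------------------------
# contact maps


def _loop_boost_pixels(
    config: CohortSimConfig, truth: CohortTruth, group: str, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, boost) for pixels near loops planted in this group's classes."""
    sigma = config.loop_spill
    phi = config.loop_enrichment
    K = max(1, int(math.ceil(3 * sigma)))
    offs = np.arange(-K, K + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    kernel = np.exp(-(di**2 + dj**2) / (2 * sigma**2))
    wanted = {"shared", f"{group}_specific"}
    ii, jj, bb = [], [], []
    for lp in truth.loops:
        if lp.klass not in wanted:
            continue
        pi = lp.bin1 + di
        pj = lp.bin2 + dj
        boost = 1.0 + (phi - 1.0) * kernel
        ok = (pi >= 0) & (pj >= 0) & (pi < n) & (pj < n) & (pi < pj)
        ii.append(pi[ok])
        jj.append(pj[ok])
        bb.append(boost[ok])
    if not ii:
        z = np.array([], dtype=np.int64)
        return z, z.copy(), np.array([])
    return (np.concatenate(ii), np.concatenate(jj), np.concatenate(bb))


def simulate_contact_map(
    config: CohortSimConfig,
    truth: CohortTruth,
    group: str,
    sample_seed: int,
) -> BinnedContactMap:
    """Draw one raw (unbalanced) cis contact map for one sample.

    Identical (config, truth, group, sample_seed) yield identical maps.
    """
    res = config.resolution
    n = -(-config.chrom_length // res)
    ratio = config.compartment_resolution // res
    lab = truth.compartment_labels[group][(np.arange(n) // ratio)]
    s = config.compartment_strength
    alpha = config.decay_exponent
    base = (np.arange(n, dtype=float) + 1.0) ** (-alpha)

    bi, bj, boost = _loop_boost_pixels(config, truth, group, n)

    # normalization Z: total expectation of the unscaled intensity
    z = 0.0
    for d in range(n):
        same = lab[: n - d] == lab[d:]
        c_sum = same.sum() * s + (n - d - same.sum()) / s
        z += base[d] * c_sum
    c_loop = np.where(lab[bi] == lab[bj], s, 1.0 / s)
    z += float(np.sum(base[bj - bi] * c_loop * (boost - 1.0)))
    scale = config.depth / z if z > 0 else 0.0

    rng = np.random.default_rng(sample_seed)
    out_i, out_j, out_v = [], [], []
    for d in range(n):
        c_vec = np.where(lab[: n - d] == lab[d:], s, 1.0 / s)
        lam = scale * base[d] * c_vec
        draw = rng.poisson(lam)
        nz = np.nonzero(draw)[0]
        if len(nz):
            out_i.append(nz)
            out_j.append(nz + d)
            out_v.append(draw[nz].astype(float))
    # redraw loop-neighborhood pixels at their boosted intensity
    if len(bi):
        lam_loop = scale * base[bj - bi] * c_loop * boost
        loop_draw = rng.poisson(lam_loop)
        loop_keys = bi * n + bj
        if out_i:
            i_all = np.concatenate(out_i)
            j_all = np.concatenate(out_j)
            v_all = np.concatenate(out_v)
            keep = ~np.isin(i_all * n + j_all, loop_keys)
            i_all, j_all, v_all = i_all[keep], j_all[keep], v_all[keep]
        else:
            i_all = np.array([], dtype=np.int64)
            j_all = i_all.copy()
            v_all = np.array([])
        nz = loop_draw > 0
        i_all = np.concatenate([i_all, bi[nz]])
        j_all = np.concatenate([j_all, bj[nz]])
        v_all = np.concatenate([v_all, loop_draw[nz].astype(float)])
    elif out_i:
        i_all = np.concatenate(out_i)
        j_all = np.concatenate(out_j)
        v_all = np.concatenate(out_v)
    else:
        i_all = np.array([], dtype=np.int64)
        j_all = i_all.copy()
        v_all = np.array([])
    return BinnedContactMap(
        config.genome, res, {config.chrom_name: (i_all, j_all, v_all)}, balanced=False
    )


def simulate_cohort(
    config: CohortSimConfig, truth: Optional[CohortTruth] = None
) -> tuple[list[CohortSample], CohortTruth]:
    """Simulate raw contact maps for every sample of the two-group cohort."""
    if truth is None:
        truth = make_truth(config)
    samples = []
    for idx, (sample_id, group) in enumerate(config.sample_ids()):
        seed = derive_sample_seed(config.seed, idx)
        cmap = simulate_contact_map(config, truth, group, seed)
        samples.append(CohortSample(sample_id, group, cmap))
    return samples, truth


# ---------------------------------------------------------------------------
# genes, expression, CREs, phasing


def make_gene_annotation(
    config: CohortSimConfig, truth: CohortTruth, frac_at_anchors: float = 0.3
) -> list[GenomicInterval]:
    """Gene annotation covering the simulated chromosome.

    A fraction of genes is placed adjacent to planted loop anchors (cycling
    over all truth loops) so each loop class has linkable genes; the rest
    are uniform. Strands alternate; they are annotation-only.
    """
    rng = _rng(config.seed, _STREAM_GENES)
    res = config.resolution
    w = config.gene_width
    genes: list[GenomicInterval] = []
    n_at = int(round(frac_at_anchors * config.n_genes)) if truth.loops else 0
    anchors = []
    for lp in truth.loops:
        anchors.append(lp.bin1 * res)
        anchors.append(lp.bin2 * res)
    for g in range(config.n_genes):
        if g < n_at and anchors:
            a = anchors[g % len(anchors)]
            # start inside the anchor bin so the gene overlaps it directly
            start = a + int(rng.integers(0, res - w))
        else:
            start = int(rng.integers(0, config.chrom_length - w))
        genes.append(
            GenomicInterval(
                config.chrom_name, start, start + w,
                name=f"gene{g:04d}", strand="+" if g % 2 == 0 else "-",
            )
        )
    return genes


def _linked_classes(
    config: CohortSimConfig, truth: CohortTruth, genes: Sequence[GenomicInterval]
) -> dict[str, tuple[str, list[str]]]:
    """Gene -> (loop class, loop ids) for genes within the link flank of a
    group-specific anchor. Genes hitting both classes are ambiguous and get
    no planted effect."""
    from .intervals import IntervalIndex  # local import avoids cycle at init

    res = config.resolution
    links: dict[str, tuple[str, list[str]]] = {}
    per_class: dict[str, dict[str, list[str]]] = {}
    for klass in ("A_specific", "B_specific"):
        hits: dict[str, list[str]] = {}
        for lp in truth.loops_of(klass):
            a1, a2 = lp.anchors(res, config.chrom_length)
            idx = IntervalIndex([a1, a2])
            for gene in genes:
                gx = gene.expanded(config.gene_link_flank)
                if idx.overlaps_interval(gx):
                    hits.setdefault(gene.name, []).append(lp.loop_id)
        per_class[klass] = hits
    both = set(per_class["A_specific"]) & set(per_class["B_specific"])
    for klass, hits in per_class.items():
        for gene_id, loop_ids in hits.items():
            if gene_id not in both:
                links[gene_id] = (klass, loop_ids)
    return links


def simulate_expression_and_cres(
    config: CohortSimConfig,
    truth: CohortTruth,
    genes: Sequence[GenomicInterval],
) -> tuple[ExpressionTable, dict[str, list[GenomicInterval]]]:
    """FPKM expression table plus per-group CRE interval sets.

    Genes within the link flank of a group-specific anchor have their group
    mean shifted by ``expr_effect`` log2 units in that group; all genes get
    i.i.d. Gaussian log2 noise (SD ``expr_noise_sd``), back-transformed to
    FPKM. A ``cre_signal_frac`` fraction of each group's CREs is centered
    on that group's specific anchors; the rest are uniform.
    """
    links = _linked_classes(config, truth, genes)
    truth.gene_links = dict(links)
    rng = _rng(config.seed, _STREAM_EXPR)
    gene_ids = [g.name for g in genes]
    mu = rng.uniform(2.0, 7.0, size=len(genes))
    sample_ids = config.sample_ids()
    log2x = np.empty((len(genes), len(sample_ids)))
    class_of_group = {config.group_a: "A_specific", config.group_b: "B_specific"}
    for col, (sid, group) in enumerate(sample_ids):
        shift = np.array(
            [
                config.expr_effect
                if links.get(gid, (None,))[0] == class_of_group[group]
                else 0.0
                for gid in gene_ids
            ]
        )
        noise = rng.normal(0.0, config.expr_noise_sd, size=len(genes))
        log2x[:, col] = mu + shift + noise
    values = pd.DataFrame(
        np.power(2.0, log2x), index=gene_ids, columns=[s for s, _ in sample_ids]
    )
    table = ExpressionTable(values, dict(sample_ids))

    cre_rng = _rng(config.seed, _STREAM_CRES)
    res = config.resolution
    w = config.cre_width
    cres: dict[str, list[GenomicInterval]] = {}
    for group, klass in class_of_group.items():
        anchors = []
        for lp in truth.loops_of(klass):
            anchors.append((lp.bin1 * res + res // 2))
            anchors.append((lp.bin2 * res + res // 2))
        n_sig = int(round(config.cre_signal_frac * config.n_cres)) if anchors else 0
        ivs = []
        for k in range(config.n_cres):
            if k < n_sig:
                center = anchors[k % len(anchors)]
                start = max(0, center - w // 2)
            else:
                start = int(cre_rng.integers(0, config.chrom_length - w))
            ivs.append(GenomicInterval(config.chrom_name, start, start + w))
        cres[group] = ivs
    return table, cres


def make_phasing_track(config: CohortSimConfig, truth: CohortTruth) -> dict[str, np.ndarray]:
    """Phasing values (+1/-1 by planted compartment label, plus noise) per
    compartment-resolution bin. Mimics a GC-content track: one track for the
    whole cohort, based on the group-A labels."""
    rng = _rng(config.seed, _STREAM_PHASING)
    lab = truth.compartment_labels[config.group_a].astype(float)
    noise = rng.normal(0.0, config.phasing_noise_sd, size=len(lab))
    return {config.chrom_name: lab + noise}
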