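"""Shared fixtures: small deterministic maps and the default study cohort.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from loopdiff import (
    AnalysisConfig,
    BinnedContactMap,
    CohortSimConfig,
    Genome,
    analyze_cohort,
    CohortData,
)
from loopdiff.simulate import (
    make_gene_annotation,
    make_phasing_track,
    simulate_cohort,
    simulate_expression_and_cres,
)


def make_decay_map(
    n_bins: int = 60,
    resolution: int = 10_000,
    scale: float = 120.0,
    chrom: str = "chrT",
    planted: dict[tuple[int, int], float] | None = None,
    balanced: bool = True,
) -> BinnedContactMap:
    """Deterministic loop-free decay map: value(d) = round(scale / (d+1)),
    optionally with pixels multiplied by a planted factor. Marked balanced
    with unit biases so it can feed the calling stage directly."""
    genome = Genome([(chrom, n_bins * resolution)])
    ii, jj, vv = [], [], []
    for i in range(n_bins):
        for j in range(i, n_bins):
            v = round(scale / (j - i + 1))
            if planted and (i, j) in planted:
                v = v * planted[(i, j)]
            if v > 0:
                ii.append(i)
                jj.append(j)
                vv.append(float(v))
    bias = {chrom: np.ones(n_bins)} if balanced else None
    return BinnedContactMap(
        genome,
        resolution,
        {chrom: (np.array(ii), np.array(jj), np.array(vv, dtype=float))},
        balanced=balanced,
        bias=bias,
    )


def make_uniform_map(
    n_bins: int = 40, resolution: int = 10_000, value: float = 2.0,
    chrom: str = "chrU",
) -> BinnedContactMap:
    """Every pixel filled with the same value: O/E is exactly 1 everywhere."""
    genome = Genome([(chrom, n_bins * resolution)])
    i, j = np.triu_indices(n_bins)
    return BinnedContactMap(
        genome,
        resolution,
        {chrom: (i, j, np.full(len(i), value))},
        balanced=True,
        bias={chrom: np.ones(n_bins)},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort (4 vs 4, 50 Mb at 10 kb,
    40 shared + 30 + 30 specific loops, 8-fold enrichment, depth 1e7) with
    the full analysis run at the default thresholds. Shared session-wide:
    every consumer treats it as read-only."""
    sim = CohortSimConfig(seed=1)
    samples, truth = simulate_cohort(sim)
    genes = make_gene_annotation(sim, truth)
    expr, cres = simulate_expression_and_cres(sim, truth, genes)
    phasing = make_phasing_track(sim, truth)
    data = CohortData(
        samples=samples, groups=(sim.group_a, sim.group_b),
        phasing=phasing, cres=cres, expression=expr, genes=genes,
    )
    results = analyze_cohort(data, AnalysisConfig(seed=1))
    return {
        "sim": sim,
        "truth": truth,
        "data": data,
        "results": results,
    }
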