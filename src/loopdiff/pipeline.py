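"""End-to-end orchestration: simulate/load -> balance -> call -> consensus
-> APA -> compartments -> enrichment -> gene linking, with deterministic
seeding and a run manifest.

All stage outputs are pure functions of (inputs, config, seed); the
manifest records every threshold, the derived seeds and the SHA-256 of
every file written, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as ldio
from .annotate import (
    differential_expression,
    link_genes,
    permutation_enrichment,
)
from .apa import compare_apa_groups, pileup
from .balance import coarsen, compute_expected, ice_balance
from .calling import call_loops
from .compartments import (
    cluster_samples,
    compartment_eigenvector,
    variable_bin_correlation,
)
from .core import BinnedContactMap, ExpressionTable, GenomicInterval
from .differential import (
    ConsensusLoopReport,
    gained_loops_for_sample,
    pairwise_differential,
    subtype_enriched_loops,
)
from .simulate import (
    CohortSimConfig,
    CohortSample,
    make_gene_annotation,
    make_phasing_track,
    simulate_cohort,
    simulate_expression_and_cres,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "CohortData", "run_full", "analyze_cohort"]


@dataclass
class AnalysisConfig:
    """All analysis thresholds; defaults are the study's stated parameters."""

    resolution: int = 10_000
    compartment_resolution: int = 100_000
    fdr_call: float = 0.05
    max_sparsity: float = 0.8
    fdr_diff: float = 0.001
    min_ratio: float = 1.5
    min_pairwise: int = 2
    min_samples: int = 2
    apa_window_bins: int = 5
    gene_flank: int = 3_000
    n_perm: int = 1_000
    de_p: float = 0.05
    de_lfc: float = 1.0
    top_variable_frac: float = 0.25
    tol_bins: int = 1
    min_dist: int = 60_000
    max_dist: int = 2_000_000
    seed: int = 0

    def validate(self, n_a: int, n_b: int) -> None:
        if self.min_samples > max(n_a, n_b):
            raise ValueError(
                f"min_samples={self.min_samples} exceeds group size "
                f"({n_a} vs {n_b})"
            )
        if self.compartment_resolution % self.resolution:
            raise ValueError(
                "compartment_resolution must be a multiple of resolution"
            )


@dataclass
class CohortData:
    """In-memory cohort: raw maps plus the matched annotation inputs."""

    samples: list[CohortSample]  # raw (unbalanced) maps at loop resolution
    groups: tuple[str, str]
    phasing: dict[str, np.ndarray]  # per compartment-resolution bin
    cres: dict[str, list[GenomicInterval]]
    expression: Optional[ExpressionTable] = None
    genes: Optional[list[GenomicInterval]] = None


def _enrichment_seed(seed: int, k: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(1000 + k,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def analyze_cohort(
    data: CohortData, config: AnalysisConfig, out_dir: Optional[Path] = None
) -> dict:
    """Run every analysis stage on an in-memory cohort.

    Returns a result dictionary; when ``out_dir`` is given, per-stage
    outputs and a manifest are also written there.
    """
    group_a, group_b = data.groups
    in_a = [s for s in data.samples if s.group == group_a]
    in_b = [s for s in data.samples if s.group == group_b]
    config.validate(len(in_a), len(in_b))

    # stage 1-2: compartment-resolution copies, balancing, expected, calls
    factor = config.compartment_resolution // config.resolution
    balanced: dict[str, BinnedContactMap] = {}
    expected = {}
    comp_balanced = {}
    comp_expected = {}
    loops = {}
    for s in data.samples:
        comp_raw = coarsen(s.cmap, factor)
        cb, _ = ice_balance(comp_raw)
        comp_balanced[s.sample_id] = cb
        comp_expected[s.sample_id] = compute_expected(cb)
        bal, _ = ice_balance(s.cmap)
        balanced[s.sample_id] = bal
        expected[s.sample_id] = compute_expected(bal)
        loops[s.sample_id] = call_loops(
            bal,
            expected[s.sample_id],
            fdr=config.fdr_call,
            min_dist=config.min_dist,
            max_dist=config.max_dist,
            max_sparsity=config.max_sparsity,
            sample_id=s.sample_id,
        )
        logger.info("%s: %d loops called", s.sample_id, len(loops[s.sample_id]))

    # stage 3: pairwise differential + two-level consensus
    reports: dict[str, ConsensusLoopReport] = {}
    for group, own, other in ((group_a, in_a, in_b), (group_b, in_b, in_a)):
        per_sample = {}
        for sx in own:
            pws = [
                pairwise_differential(
                    loops[sx.sample_id],
                    balanced[sx.sample_id],
                    balanced[sy.sample_id],
                    expected[sx.sample_id],
                    expected[sy.sample_id],
                    fdr_diff=config.fdr_diff,
                    min_ratio=config.min_ratio,
                    call_fdr=config.fdr_call,
                    match_window=config.tol_bins,
                    sample_x=sx.sample_id,
                    sample_y=sy.sample_id,
                )
                for sy in other
            ]
            per_sample[sx.sample_id] = gained_loops_for_sample(
                sx.sample_id,
                pws,
                config.resolution,
                min_pairwise=config.min_pairwise,
                tol_bins=config.tol_bins,
            )
        reports[group] = subtype_enriched_loops(
            per_sample,
            config.resolution,
            group=group,
            min_samples=config.min_samples,
            min_pairwise=config.min_pairwise,
            tol_bins=config.tol_bins,
        )
        logger.info("%s: %d subtype-enriched loops", group, len(reports[group]))

    # stage 4: APA of each group's enriched loops across all samples
    apa_scores: dict[str, dict[str, float]] = {}
    apa_p: dict[str, float] = {}
    for group, own, other in ((group_a, in_a, in_b), (group_b, in_b, in_a)):
        enriched = [c.loop for c in reports[group].loops]
        scores = {}
        if enriched:
            for s in data.samples:
                pile = pileup(
                    balanced[s.sample_id],
                    expected[s.sample_id],
                    enriched,
                    window_bins=config.apa_window_bins,
                )
                scores[s.sample_id] = pile.apa_score
            own_scores = [scores[s.sample_id] for s in own]
            other_scores = [scores[s.sample_id] for s in other]
            apa_p[group] = compare_apa_groups(
                own_scores, other_scores, alternative="greater"
            )
        apa_scores[group] = scores

    # stage 5: compartments
    tracks = [
        compartment_eigenvector(
            comp_balanced[s.sample_id],
            comp_expected[s.sample_id],
            data.phasing,
            sample_id=s.sample_id,
        )
        for s in data.samples
    ]
    corr = variable_bin_correlation(tracks, top_frac=config.top_variable_frac)
    linkage, flat = cluster_samples(corr, k=2)

    # stage 6: CRE enrichment (each group's loops vs each CRE set)
    enrichment = {}
    for k, group in enumerate((group_a, group_b)):
        enriched = [c.loop for c in reports[group].loops]
        if not enriched:
            continue
        for k2, (cre_name, cre_set) in enumerate(sorted(data.cres.items())):
            res = permutation_enrichment(
                enriched,
                cre_set,
                data.samples[0].cmap.genome,
                n_perm=config.n_perm,
                seed=_enrichment_seed(config.seed, 2 * k + k2),
            )
            enrichment[f"{group}_loops_vs_{cre_name}_cres"] = res

    # stage 7: gene linking + differential expression
    gene_tables = {}
    deg = None
    if data.genes is not None:
        for group in (group_a, group_b):
            enriched = [c.loop for c in reports[group].loops]
            gene_tables[group] = (
                link_genes(enriched, data.genes, flank=config.gene_flank)
                if enriched
                else pd.DataFrame(columns=["gene"])
            )
    if data.expression is not None:
        deg = differential_expression(
            data.expression, group_a, group_b,
            p_thresh=config.de_p, lfc_thresh=config.de_lfc,
        )

    results = {
        "config": config,
        "loops": loops,
        "reports": reports,
        "apa_scores": apa_scores,
        "apa_p": apa_p,
        "eigentracks": tracks,
        "sample_correlation": corr,
        "cluster_labels": flat,
        "linkage": linkage,
        "enrichment": enrichment,
        "linked_genes": gene_tables,
        "deg": deg,
    }
    if out_dir is not None:
        _write_outputs(results, data, Path(out_dir))
    return results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(results: dict, data: CohortData, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sid, ls in results["loops"].items():
        p = out_dir / f"loops_{sid}.bedpe"
        ldio.write_bedpe(ls, p)
        written.append(p)
    for group, report in results["reports"].items():
        p = out_dir / f"enriched_loops_{group}.bedpe"
        ldio.write_bedpe([c.loop for c in report.loops], p)
        written.append(p)
        prov = out_dir / f"enriched_loops_{group}_provenance.tsv"
        with open(prov, "w") as fh:
            fh.write("chrom\tstart1\tstart2\tsample\tcomparisons\n")
            for c in report.loops:
                for sample, tags in c.support.items():
                    fh.write(
                        f"{c.loop.chrom}\t{c.loop.anchor1.start}\t"
                        f"{c.loop.anchor2.start}\t{sample}\t{','.join(tags)}\n"
                    )
        written.append(prov)
    for t in results["eigentracks"]:
        p = out_dir / f"eigentrack_{t.sample_id}.bedgraph"
        ldio.write_eigentrack(t, p)
        written.append(p)
    p = out_dir / "sample_correlation.tsv"
    results["sample_correlation"].to_csv(p, sep="\t")
    written.append(p)
    if results["deg"] is not None:
        p = out_dir / "differential_expression.tsv"
        results["deg"].to_csv(p, sep="\t")
        written.append(p)
    summary = {
        "config": asdict(results["config"]),
        "groups": list(data.groups),
        "n_loops_per_sample": {s: len(l) for s, l in results["loops"].items()},
        "n_enriched_loops": {g: len(r) for g, r in results["reports"].items()},
        "apa_scores": results["apa_scores"],
        "apa_p": results["apa_p"],
        "cluster_labels": results["cluster_labels"],
        "enrichment": {
            k: {"observed_fraction": v.observed_fraction, "p": v.p_empirical,
                "n_perm": v.n_perm, "seed": v.seed}
            for k, v in results["enrichment"].items()
        },
    }
    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)
    manifest = {
        "files": {f.name: _sha256(f) for f in sorted(written)},
        "seed": results["config"].seed,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run_full(
    config: AnalysisConfig,
    out_dir: Path,
    sim_config: Optional[CohortSimConfig] = None,
    data: Optional[CohortData] = None,
    write_maps: bool = False,
) -> dict:
    """Run the full pipeline, either on a simulated cohort (``sim_config``)
    or on pre-loaded inputs (``data``)."""
    if (sim_config is None) == (data is None):
        raise ValueError("provide exactly one of sim_config or data")
    if sim_config is not None:
        samples, truth = simulate_cohort(sim_config)
        genes = make_gene_annotation(sim_config, truth)
        expr, cres = simulate_expression_and_cres(sim_config, truth, genes)
        phasing = make_phasing_track(sim_config, truth)
        data = CohortData(
            samples=samples,
            groups=(sim_config.group_a, sim_config.group_b),
            phasing=phasing,
            cres=cres,
            expression=expr,
            genes=genes,
        )
        if write_maps:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for s in samples:
                ldio.write_contact_map(s.cmap, out / f"map_{s.sample_id}.coo.tsv")
        results = analyze_cohort(data, config, Path(out_dir))
        results["truth"] = truth
        return results
    return analyze_cohort(data, config, Path(out_dir))
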