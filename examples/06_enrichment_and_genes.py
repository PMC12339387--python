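"""CRE-overlap enrichment and loop-gene expression integration.

Tests whether group-A-enriched loops overlap group-A CREs more than
chromosome-matched random anchors (1,000 permutations, add-one empirical
p), links genes within +/-3 kb of loop anchors, and flags differential
expression (two-sided t on FPKM, p < 0.05 and |log2FC| >= 1).
"""

from loopdiff import (
    CohortSimConfig, GenomicInterval, LoopCall,
    differential_expression, link_genes, permutation_enrichment,
    simulate_cohort,
)
from loopdiff.simulate import make_gene_annotation, simulate_expression_and_cres

sim = CohortSimConfig(
    seed=0, chrom_length=8_000_000, depth=2e6,
    n_shared=4, n_a_specific=3, n_b_specific=3,
    min_loop_span=150_000, max_loop_span=600_000,
    n_genes=120, n_cres=60,
)
samples, truth = simulate_cohort(sim)
genes = make_gene_annotation(sim, truth)
expr, cres = simulate_expression_and_cres(sim, truth, genes)

res = sim.resolution
a_loops = [
    LoopCall(GenomicInterval(lp.chrom, lp.bin1 * res, (lp.bin1 + 1) * res),
             GenomicInterval(lp.chrom, lp.bin2 * res, (lp.bin2 + 1) * res))
    for lp in truth.loops_of("A_specific")
]

for cre_group in ("A", "B"):
    out = permutation_enrichment(a_loops, cres[cre_group], sim.genome,
                                 n_perm=1000, seed=0)
    print(f"A loops vs {cre_group}-CREs: observed fraction "
          f"{out.observed_fraction:.2f}, permutation p = {out.p_empirical:.4g}")

linked = link_genes(a_loops, genes, flank=3000)
deg = differential_expression(expr, "A", "B")
merged = linked.join(deg, on="gene")
print(f"\n{len(linked)} genes within 3 kb of A-loop anchors:")
print(merged[["gene", "log2fc", "p_value", "significant"]]
      .round(3).to_string(index=False))
print("\nGenes linked to A-specific loops carry the planted ~2 log2FC; the "
      "small p and large fold change mark them significant.")
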