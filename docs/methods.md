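# Methods

This note documents the models, parameter choices and numerical
conventions behind `loopdiff`, and what the synthetic validation does and
does not demonstrate.

## Coordinates, containers, formats

All intervals are 0-based half-open (BED convention), including loop
anchors; overlap means ≥ 1 shared bp, so `[a,b)` and `[b,c)` never
overlap. Contact maps are cis-only and stored as upper-triangle sparse
pixels (`bin_i ≤ bin_j`) at a fixed resolution; trans pairs in BEDPE
input are skipped with a logged count. The portable map format is a
plain-text COO dialect with `#resolution=` and `#balanced=` headers (and
an optional `#bias:` header carrying balancing factors); no binary
container format is used. Strand is parsed but ignored for anchors and
CREs; gene strand is kept for annotation only.

## Balancing and expected profile

Iterative correction repeats `b_i ← b_i · m_i / mean(m)` over mappable
bins (dividing pixels by `b_i b_j`) until the maximum relative marginal
deviation is below `tol` (default 1e-5, `max_iter` 200 — chosen here as a
reproducible convention since balancing-tool defaults vary). A *mappable*
bin is one with nonzero raw marginal; masked bins get NaN bias and are
excluded from the expected profile, eigenvectors, APA and loop tests.
The bias is rescaled to mean 1 over mappable bins (any fixed scale is
valid; this one makes balanced values commensurate with raw counts via
`raw = balanced · b_i b_j`). The expected value `e[d]` is the mean
balanced value over *all* mappable bin pairs at bin distance `d` —
absent pixels count as zeros (sum/n_pairs, not sum/nnz), which is what
makes O/E unbiased on sparse maps.

## Loop calling

The caller is a deterministic HiCCUPS-style multi-neighborhood Poisson
test, a documented stand-in for scale-space blob detection; external
BEDPE loop lists can be substituted at every downstream stage.
Candidates are pixels with O/E ≥ 1.5 at genomic distance within
[`min_dist`, `max_dist`] (defaults 60 kb – 2 Mb; the lower bound is
`(bg_outer + 1) · resolution` so the background ring clears the
diagonal). For each candidate the local background is
`e[d] ·` max over four neighborhood mean-O/E values — donut (square ring
between `bg_inner = 2` and `bg_outer = 5`, center row/column excluded),
lower-left quadrant, horizontal and vertical 3-wide strips — computed
with integral images over the dense symmetric O/E matrix; invalid cells
(masked bins, out of range) are excluded from the means. The p-value is
the Poisson upper tail of the raw-equivalent observed
(`balanced · b_i b_j`, rounded) at the raw-rescaled background rate.
Candidates whose `(2·bg_outer+1)²` neighborhood has a zero fraction
above `max_sparsity = 0.8` (computed over valid cells) are dropped —
the sparsity-threshold semantics adopted here for the published
threshold value. BH correction runs across all tested pixels; adjacent
significant pixels (8-connectivity) merge into one call keeping the
highest-observed pixel, ties to the lexicographically smallest bin pair.

## Pairwise differential test and two-level consensus

The differential rule between sample X and sample Y, for each loop
called in X at q ≤ 0.05: find the best-matching pixel within ±1 bin in Y
(maximum O/E — deliberately giving Y the benefit of the doubt), then
test equality of O/E rates with a conditional binomial:
`k_x | k_x + k_y ~ Binomial(k_x + k_y, λ_x / (λ_x + λ_y))`, one-sided
toward X, where `k` are raw-equivalent counts and `λ` the raw-rescaled
local backgrounds. Counts and background rates are aggregated over a
3 × 3 window (`agg_window = 1`) centered on the matched pixel: a loop's
counts are spread over adjacent pixels, and at realistic depths the
center pixel alone carries too few raw pairs for the binomial tail to
reach stringent FDR levels even for large effects (the smallest
attainable p is ~2^−(k_x+k_y)); the window aggregates the blob-level
evidence the way scale-space differential callers do. `agg_window = 0`
restores the single-pixel test. BH at FDR 0.001 is applied per pairwise
comparison (not pooled), plus an O/E ratio floor of 1.5.

Consensus level 1: a loop is *gained* by sample X when it appears
(matching both anchors within `tol_bins = 1`) in ≥ `min_pairwise = 2` of
X's comparisons against the opposite group. Level 2: a loop is
*subtype-enriched* when gained in ≥ `min_samples = 2` samples of the
group. Cross-sample loop identity uses greedy clustering against cluster
representatives (most frequent exact coordinates, ties to the
lexicographically smallest); exact matching is available via
`tol_bins = 0`. Full provenance (which samples, which comparisons) is
recorded per consensus loop.

## APA

Pileups average `window_bins × window_bins` (default 5, i.e. 50 kb ×
50 kb at 10 kb) O/E submatrices centered on loop pixels; loops whose
window crosses a chromosome edge, touches the diagonal (any cell with
`bin_i ≥ bin_j`) or overlaps a masked bin are skipped and counted — the
conditions under which O/E cells would be undefined. The APA score is
the arithmetic mean of the central 3 × 3 cells. Group contrasts use the
pooled-variance (Student's) two-sample t test, one-sided, on per-sample
scores; Welch is available by flag; two constant equal score lists give
p = 0.5 by the t = 0 convention.

## Compartments

Per chromosome, the O/E matrix over mappable bins is clipped to
[0.01, 100] (taming sparse-bin outliers), converted to a Pearson
correlation matrix across bin profiles, and the eigenvector of the
largest-|λ| eigenvalue, scaled by √|λ|, is the compartment track
(`use_corr=False` decomposes O/E − 1 directly, the convention of some
tools). The sign is flipped when the track correlates negatively with
the phasing track, so "positive = phasing-high" consistently;
chromosomes with < 10 mappable bins are skipped, and degenerate
correlation matrices (uniform O/E) yield an all-zero track with a flag.
Sample relatedness: bins defined and nonzero in every track are ranked
by across-sample variance; the top 25 % enter pairwise Pearson
correlations; hierarchical clustering uses average linkage on 1 − r
(samples pre-sorted lexicographically for deterministic tie-breaks).

## Enrichment, gene linking, expression

The CRE statistic is the fraction of loops with either anchor
overlapping ≥ 1 CRE (an anchor-level variant is provided; the loop-level
form is the default). The null resamples every anchor uniformly on its
own chromosome with identical width, keeping loop pairing; the empirical
p uses the add-one estimator `p = (1 + #{null ≥ obs}) / (n_perm + 1)`
(1,000 permutations by default, so the p floor is ~0.001). Null anchors
are unrestricted by default; a mappable-bin-restricted mode is a flag.
Gene linking takes the gene body ± 3 kb (TSS-only by flag) against all
anchors. Differential expression is a two-sided pooled t test per gene
on FPKM between the groups with `log2FC = log2((mean_A + ε)/(mean_B + ε))`,
ε = 0.1 FPKM for stability near zero; significance needs p < 0.05 and
|log2FC| ≥ 1. TF-anchored loop annotation keeps loops where every
required peak set hits ≥ 1 anchor (a both-anchors mode is a flag) and
then removes loops matching an exclusion list within `tol_bins`.

## Synthetic cohort generator

The generator defines the validation conditions. Pixel means are
`λ_ij = depth · Z⁻¹ · (|i−j|+1)^−α · B_ij · C_ij` with independent
Poisson counts; `Z` normalizes the total expectation to `depth`.
Defaults: one 50 Mb chromosome at 10 kb (5,000 bins), 4 + 4 samples,
`depth = 1e7` cis pairs, decay exponent α = 1 (a typical cis decay
slope), 40 shared + 30 + 30 group-specific loops with enrichment
φ = 8 spread by a Gaussian of σ = 0.75 bins, spans 200 kb – 1.5 Mb,
compartment blocks of 2.5 Mb at strength 1.5 (same-label pairs × 1.5,
cross-label ÷ 1.5, applied at 100 kb label granularity), 25 % of blocks
flipping label between groups, expression effect 2 log2 units with
noise SD 0.25, 600 genes, 300 CREs of 2 kb per group with half centered
on group-specific anchors.

Design points worth recording:

* **Per-group compartment labels.** The truth carries one label track
  per group with a fraction of blocks flipped; without a group-level
  compartment difference all samples would be statistically
  exchangeable at 100 kb and no clustering method could separate the
  groups. The phasing track is built from the group-A labels plus noise
  — it mimics GC content, a genome-level quantity, and with a flip
  fraction < 0.5 it orients both groups' eigenvectors consistently.
* **Shared loops avoid flipped blocks.** A "shared" loop whose anchor
  pair has same-label parity in one group and cross-label parity in the
  other would inherit the s² compartment contrast and not actually be
  shared in strength; placement therefore requires concordant parity
  across groups for shared loops (group-specific loops are
  unconstrained).
* **Collision-free placement.** Planted pixels keep a Chebyshev
  distance > 12 bins from each other and from chromosome edges, so no
  loop sits in another's APA window or background ring.
* Per-sample seeds derive from the root seed through named
  `SeedSequence` substreams; the full cohort is byte-reproducible from
  `config.seed`.

What the generator does *not* emulate: overdispersion beyond Poisson,
restriction-fragment structure, trans contacts, translocation-driven
neo-loops, TADs/stripes, mappability gaps, and distance-dependent
technical noise. Passing tests on this cohort therefore demonstrate the
correctness and calibration of the statistical machinery under the
stated generative model, not performance on real tumor Hi-C.

## Problem sizes and determinism

The validation cohort (8 samples × 5,000 bins at depth 1e7) was chosen
as the largest desk-scale configuration: the full pipeline runs in
about two minutes on one CPU. The permutation-calibration experiment
uses 200 replicates of 300 loops vs 400 random CREs at 1,000
permutations. All randomness flows from explicit integer seeds; reruns
with the same configuration produce byte-identical outputs (the
pipeline writes a manifest with SHA-256 hashes to make this checkable).

## Known limitations

* The loop caller is a local-background test, not a scale-space
  detector; very broad or nested enrichment structures merge into
  single calls.
* The differential test conditions on local backgrounds estimated from
  each map; systematic coverage differences between samples are
  absorbed by balancing, but copy-number-driven local effects are not
  modeled.
* Compartment eigenvectors on short chromosomes (< 10 mappable bins)
  are skipped rather than estimated.
* FPKM t tests are the integration-level convention here; count-based
  differential expression (negative binomial) is out of scope.
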