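"""Aggregate peak analysis: pile up loops and contrast groups.

Piles the planted A-specific loops on every sample's balanced map
(5 x 5 bins = 50 kb x 50 kb O/E window), reports the APA score (mean of
the central 3 x 3) per sample, and tests A vs B scores with a one-sided
Student's t test. An APA score near 1 means no focal enrichment.
"""

import numpy as np

from loopdiff import (
    CohortSimConfig, GenomicInterval, LoopCall,
    apa_score, compare_apa_groups, compute_expected, ice_balance, pileup,
    simulate_cohort,
)

sim = CohortSimConfig(
    seed=0, chrom_length=8_000_000, depth=2e6,
    n_shared=4, n_a_specific=3, n_b_specific=3,
    min_loop_span=150_000, max_loop_span=600_000,
)
samples, truth = simulate_cohort(sim)
res = sim.resolution
a_loops = [
    LoopCall(GenomicInterval(lp.chrom, lp.bin1 * res, (lp.bin1 + 1) * res),
             GenomicInterval(lp.chrom, lp.bin2 * res, (lp.bin2 + 1) * res))
    for lp in truth.loops_of("A_specific")
]

scores = {}
for s in samples:
    balanced, _ = ice_balance(s.cmap)
    pile = pileup(balanced, compute_expected(balanced), a_loops, window_bins=5)
    scores[s.sample_id] = apa_score(pile)
    print(f"  {s.sample_id} ({s.group}): APA score {scores[s.sample_id]:.2f} "
          f"({pile.n_used} loops piled)")

a = [scores[s.sample_id] for s in samples if s.group == "A"]
b = [scores[s.sample_id] for s in samples if s.group == "B"]
p = compare_apa_groups(a, b, alternative="greater")
print(f"\nA-specific loops: mean APA {np.mean(a):.2f} in A vs "
      f"{np.mean(b):.2f} in B; one-sided t test p = {p:.2g}")
print("Scores >> 1 only in group A show the planted loops are focal, "
      "group-specific contacts.")
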