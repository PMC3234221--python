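"""Bisulfite read simulation and per-context methylation calling.

Assigns known per-site methylation (bimodal CpG, exponential CpA,
noise-free CpT/CpC), simulates 36 bp directional reads at 99% conversion,
calls methylation, and compares the per-context summary and the estimated
conversion rate with the generative truth.
"""

import noncpg as n

genome = n.generate_genome(30000, n_islands=4, island_len=500,
                           msp1_spacing=140, seed=1)
frags = n.size_select(n.digest_genome(genome))
truth = n.assign_methylation(genome, cpa_rate=n.CPA_MEAN_PRESETS["pluripotent"],
                             seed=2)
reads = n.simulate_reads(genome, truth, frags, mean_coverage=50,
                         conversion_rate=0.99, seed=3)
table = n.call(reads, genome, sample_id="ES_like")

print(f"{len(reads.reads)} reads -> {len(table)} called cytosines\n")
summary = n.context_summary(table, min_cov=5, meth_threshold=0.10)
print(summary.round(2))
print("\npct_methylated = sites with level >= 10% among those covered >= 5x;")
print("share_of_methylated = each context's slice of all methylated cytosines.")

est = n.estimate_conversion(table)
print(f"\nestimated conversion rate (global CpC): {est.global_cpc:.4f} "
      f"(simulated: {reads.conversion_rate})")
print("CpT/CpC truth is 0 here, so residual CpC methylation is pure "
      "conversion failure.")
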