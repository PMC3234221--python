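"""Cross-sample conservation of CpG versus CpA methylation.

Simulates six replicates from the same pluripotent-like truth, builds the
5x-in-80% consensus set, and contrasts CpG and CpA methylation with
pairwise Pearson correlations, coefficients of variation, the
coverage-capped conservation score, and an exponential fit to per-site
median CpA levels.
"""

import numpy as np

import noncpg as n

genome = n.generate_genome(30000, n_islands=4, island_len=500,
                           msp1_spacing=140, seed=1)
frags = n.size_select(n.digest_genome(genome))
truth = n.assign_methylation(genome, seed=2)
samples = [n.call(n.simulate_reads(genome, truth, frags, mean_coverage=50,
                                   seed=10 + i), genome, f"rep{i}")
           for i in range(6)]

iu = np.triu_indices(len(samples), 1)
for ctx in ("CpG", "CpA"):
    cons = n.build_consensus(samples, ctx, min_cov=5, min_sample_frac=0.8)
    r = n.pairwise_pcc(samples, cons, min_cov=5)
    part = n.evident_methylation_partition(samples, ctx)
    cv = n.coefficient_of_variation(samples, part, ctx)
    print(f"{ctx}: consensus {len(cons)} sites, "
          f"mean pairwise r = {np.nanmean(r.values[iu]):.2f}, "
          f"mean CV = {cv.mean():.2f}")
print("replicates share one truth, so all between-sample spread is "
      "sampling noise; CpA's low levels make its r low and CV high even "
      "then.")

cs = n.conservation_score(levels=[0.1, 0.2, 0.3], coverages=[10, 30, 50], cap=25)
print(f"\nconservation score example: weights {cs.weights.tolist()}, "
      f"weighted mean {cs.weighted_mean:.3f}, score {cs.score:.4f}")
print("(coverage above 25 is capped so deep samples cannot dominate)")

fit = n.fit_exponential_medians(samples, "CpA")
print(f"\nexponential fit to CpA medians: mean {fit.mean:.4f}, "
      f"KS distance {fit.ks_stat:.3f} over {fit.n} sites")
fit_g = n.fit_exponential_medians(samples, "CpG")
print(f"same fit on bimodal CpG medians: KS {fit_g.ks_stat:.3f} "
      "(much worse, as expected)")
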