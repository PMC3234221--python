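"""Feature-class aggregation and 1 kb DMR tiling.

Defines promoters around synthetic TSSs, splits them into high-CpG (HCP)
and low-CpG (LCP) classes by CG-island overlap, summarises CpA methylation
per class, then tiles a candidate region into 1 kb windows of per-sample
median CpA levels and profiles its CpG density.
"""

import numpy as np

import noncpg as n

genome = n.generate_genome(30000, n_islands=4, island_len=500,
                           msp1_spacing=140, seed=1)
frags = n.size_select(n.digest_genome(genome))
truth = n.assign_methylation(genome, seed=2)
samples = [n.call(n.simulate_reads(genome, truth, frags, mean_coverage=50,
                                   seed=20 + i), genome, f"s{i}")
           for i in range(3)]

tss = [("geneA", 8000, "+"), ("geneB", 18000, "+"), ("geneC", 10000, "-")]
promoters = n.make_promoters(tss)  # TSS-5 kb .. TSS+1 kb, strand-oriented
hcp, lcp = n.classify_promoters(promoters, genome.islands)
classes = [promoters, hcp, lcp, n.FeatureClass("CGI", genome.islands)]
agg = n.aggregate_by_feature(samples[0], classes, context="CpA")
print(agg.round(4))
print("\nper-class CpA level quartiles; island-overlapping promoters (HCP) "
      "are expected to be the most depleted.\n")

region = (5000, 15000)
profile = n.tile_dmr(region, samples, genome, tile_bp=1000, min_cov=5)
print(f"region {region}: {len(profile.tiles)} tiles, "
      f"{100 * profile.covered_frac:.1f}% of its CpAs covered >=5x in all "
      f"samples, retained={profile.retained}")
print("per-tile median CpA level (first sample):")
print(profile.medians.iloc[:, 0].round(3).to_string())

dens = n.cpg_density_profile([region], genome, n_bins=10, flank_bp=5000)
print("\nCpG density across the region (10 bins):",
      np.round(dens["body"], 3))
print("density = CpG dinucleotides per bp; dips mark CpG-poor stretches.")
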