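"""In-silico MspI digestion and reduced-representation coverage.

Generates a small genome with CG islands and CCGG sites, digests it at
C^CGG, applies the 40-260 bp size selection, and reports which fraction of
each cytosine-dinucleotide context the size-selected library can see, plus
its enrichment relative to the whole genome.
"""

import noncpg as n

genome = n.generate_genome(length=30000, gc_background=0.42, n_islands=4,
                           island_len=500, msp1_spacing=140, seed=1)
frags = n.size_select(n.digest_genome(genome, site="CCGG", cut_offset=1),
                      min_bp=40, max_bp=260)

print(f"genome: {len(genome)} bp, {genome.sequence.count('CCGG')} CCGG sites")
print(f"fragments: {len(frags)} total, {int(frags.selected.sum())} in 40-260 bp")

census = n.dinucleotide_census(genome, frags)
ratios = n.enrichment(census)
print("\ncontext  covered/total  fraction  enrichment")
for ctx in ("CpG", "CpA", "CpT", "CpC"):
    row = census.loc[ctx]
    print(f"{ctx}: {row['covered']}/{row['total']}  "
          f"{100 * row['fraction']:.1f}%  {ratios[ctx]:.2f}")
print("\nfraction = share of that context inside size-selected fragments;")
print("enrichment > 1 means the library over-represents the context "
      "relative to its genomic frequency.")
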