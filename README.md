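# noncpg

Analysis of non-CpG (CpA/CpT/CpC) versus CpG methylation from
reduced-representation bisulfite sequencing (RRBS), with a built-in
simulator so that every stage can be validated against known truth.

## The problem

In human pluripotent cells a small but reproducible fraction of DNA
methylation falls outside the canonical CpG dinucleotide, mostly on CpA.
This signal is rare (per-site levels follow a roughly exponential
distribution with mean of a few percent), poorly conserved between cell
lines, lost upon differentiation, and tied to the expression of the de
novo methyltransferases DNMT3A/DNMT3B. Measuring it from RRBS is delicate:
the protocol covers only the MspI (C^CGG) fragments that survive a
40–260 bp size selection, bisulfite conversion failure inflates apparent
methylation by roughly `1 − conversion_rate`, and cross-sample comparisons
are only meaningful on explicitly defined site sets.

`noncpg` is a library for scientists who want to run or scrutinise this
kind of analysis: it implements the full chain from in-silico digestion to
predictive models, and pairs it with a generative simulator
(`noncpg.synthetic`) whose ground truth makes each stage testable.

## What it computes

* **Digestion** (`noncpg.digest`): MspI cuts at C^CGG, inclusive 40–260 bp
  size selection, per-context dinucleotide census (both strands counted as
  distinct sites) and enrichment relative to the whole genome.
* **Calling** (`noncpg.calling`): per strand-specific cytosine, the level
  is the fraction of reads with an unconverted C; contexts come from the
  reference. Conversion rate is estimated from global CpC levels and from
  island-promoter methylation.
* **Filtering** (`noncpg.filtering`): consensus sets (coverage ≥ c in
  ≥ f of samples), named methylated-site rules (≥10% summary rule, >5%
  non-CpG / ≥30% CpG whole-methylome comparison rules, ≥5% counting rule),
  overlap statistics with Fisher exact tests, and the 0.1%-median minimal
  methylation partition.
* **Variability** (`noncpg.variation`): pairwise Pearson correlations over
  consensus sites, per-site coefficients of variation, the
  coverage-weighted conservation score
  `score = sqrt(Σw(x−μ)²/Σw) / μ` with per-sample weights
  `w = min(coverage, 25)`, exponential MLE fits to per-site median CpA
  levels with KS goodness-of-fit, reduction statistics for differentiated
  cells, and the flanking-sequence position frequency matrix of
  consistently highly methylated CpAs.
* **Regions** (`noncpg.regions`): promoter windows (TSS−5 kb..+1 kb,
  strand-oriented), HCP/LCP splits by CG-island overlap, per-class level
  summaries, 1 kb DMR tiling with the 0.5 %-of-CpAs retention rule, and
  30-bin CpG-density profiles with 1 kb flank bins.
* **Models** (`noncpg.modeling`): OLS + sequential ANOVA for the
  sample-level expression model and the tile-level models (CpG-density
  variables excluded when predicting CpA), and the site-level
  classification protocol — 30 features on ±10 bp windows, 5% methylated
  threshold, balanced down-sampling, stratified 10-fold CV AUC for
  logistic regression / linear SVM / random forest (500 trees), with
  importances from a full-data fit (Gini rescaled to max = 1).

## Worked example

`examples/02_simulate_and_call.py` simulates a pluripotent-like sample on
a 30 kb genome (exponential CpA truth, mean 0.037; conversion rate 0.99)
and calls methylation:

```
26095 reads -> 8151 called cytosines

         n_covered  n_methylated  pct_methylated  share_of_methylated
context
CpG           1859          1082           58.20                77.62
CpA           2062           287           13.92                20.59
CpT           1961            10            0.51                 0.72
CpC           1558            15            0.96                 1.08

estimated conversion rate (global CpC): 0.9901 (simulated: 0.99)
```

CpG methylation dominates (78% of methylated cytosines), CpA is the main
non-CpG signal, CpT/CpC sit at conversion-noise levels, and the planted
conversion rate is recovered to three decimals. The other example scripts
cover digestion (`01`), cross-sample variability (`03` — on shared-truth
replicates the mean pairwise CpA correlation is ~0.4 against ~0.99 for
CpG), region/DMR tiling (`04`) and the predictive models (`05`).

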