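# Methods

This note records the models, conventions and parameter choices behind
`noncpg`, and what its synthetic validation does and does not establish.

## Coordinates, sites and contexts

All intervals are 0-based half-open; SAM export is the only place 1-based
coordinates appear. A *site* is a strand-specific cytosine `(chrom, pos0,
strand)`; for minus-strand cytosines `pos0` is the position of the paired
reference G. The context (CpG/CpA/CpT/CpC) is the base immediately 3' of
the C on its own strand, always taken from the reference, never from
reads. Plus- and minus-strand cytosines are never merged: non-CpG
methylation is strand-asymmetric, and duplex merging would average away
exactly the signal of interest. (CpG duplex merging is deliberately not
performed anywhere.)

## In-silico digestion

MspI recognises CCGG and cuts after the first C. `digest` places one cut
at `occurrence_start + 1` for every (possibly overlapping) motif match;
fragments are the intervals between consecutive cuts plus the chromosome's
leading and trailing remainders, so fragment lengths always sum to the
chromosome length. Size selection keeps fragments in `[40, 260]` bp,
inclusive at both ends (the source window "40–260 bp" carries no
open/closed qualifier; inclusive is the conservative reading). A
dinucleotide belongs to a fragment only if both bases lie inside it, so
sites straddling a cut are uncovered — a real property of RRBS, since a
cut physically separates the two bases. The census tallies both strands
as distinct sites and also exposes totals, so a collapsed-duplex view can
be derived by the caller if wanted.

## Methylation calling

For each aligned read, only positions where the reference has a cytosine
on the read's strand are informative: read base C (G on minus-strand
reads, which are stored in plus orientation) increments both the
methylated and total counts, the converted base T (A) increments the total
only, and any other base — sequencing N or mismatch — increments neither.
Indel-containing alignments fall back to per-base aligned pairs so that
inserted/deleted positions are skipped. No quality filtering, read
deduplication or SNP masking is performed: RRBS fragments start at fixed
cut sites, so coordinate-based deduplication would distort coverage, and
C/T SNP masking needs external genotypes. These omissions are the main
gap between this caller and a production genotype-aware one.

Conversion rate is estimated two ways and both are reported: `1 − mean
per-site CpC level` (CpC methylation is almost entirely conversion
failure) and `1 − mean level` over supplied high-CpG island-promoter
intervals (biologically unmethylated). The estimators are unweighted over
sites; at realistic coverages the difference from read-weighted versions
is well below the estimate's own noise.

## Filtering cascades

Every cross-sample analysis states its site set explicitly:

* consensus: coverage ≥ c in ≥ f of samples, both comparisons inclusive
  (4 of 5 samples meets f = 0.8). Shipped named rules: (2x, 80%),
  (5x, 80%) for pluripotent, (5x, 70%) for differentiated cohorts,
  (10x, 80%) for the motif analysis.
* methylated-site rules, each a named `ThresholdRule` with an explicit
  comparison direction: the summary-statistics rule (≥10%, ≥5x), the
  whole-methylome comparison rules (CpG ≥30%; non-CpG **strictly** >5%,
  the one rule whose source wording — "above 5%" — implies strictness),
  and the ≥5% counting rule for differentiated cells. Keeping the
  direction in the rule object makes boundary conventions auditable.
* the minimal-methylation partition: across-sample median level ≥ 0.1%,
  medians taken over the samples where the site meets the coverage rule.
  Without it, distribution statistics are dominated by the unmethylated
  bulk.

Overlap between two methylated-site sets is evaluated only inside a
joint-coverage universe (e.g. ≥5x in both samples), with a two-sided
Fisher exact test on the 2×2 membership table (sidedness is a choice;
two-sided is the conservative default).

## Variability statistics

Pairwise Pearson correlations are computed pairwise-complete over
consensus sites. The per-site coefficient of variation uses the n−1
sample SD over the unweighted mean, computed listwise (sites covered in
every sample); zero-mean sites are flagged NaN rather than dropped or
given a sentinel. The conservation score uses per-sample weights
`w = min(coverage, 25)` — the cap stops deep samples from dominating —
with the **population**-form weighted SD `sqrt(Σw(x−μ)²/Σw)` divided by
the weighted mean; no bias correction is applied because none is defined
for this weighting. With equal sub-cap coverages the score reduces
exactly to the population-SD CV, a property the tests verify; the
deliberate n−1 vs population discrepancy between CV and score is
conventional and documented here. Listwise deletion for CV and the score
keeps the weight semantics clean; pairwise deletion is used only for
correlations.

The exponential fit to per-site median CpA levels uses the closed-form
MLE (rate = 1/mean) on positive medians, with the Kolmogorov–Smirnov
distance reported as goodness-of-fit; bimodal CpG medians fail this fit
by an order of magnitude, which is the point of reporting it.

The motif matrix collects CpAs with ≥10x coverage in ≥80% of samples and
mean level ≥15%, extracts flanks on the site's own strand (minus-strand
sites reverse-complemented), and reports per-offset base frequencies; the
anchor columns (offset 0 = C, +1 = A) are 1.0 by construction and serve
as an internal consistency check. A MEME-minimal text serialisation is
provided.

## Regions and DMR tiling

Promoters span TSS−5 kb..+1 kb oriented by gene strand; HCP/LCP is decided
by any-overlap (≥1 bp) with a CG island. Feature classes may overlap and
each receives every contained site — no precedence hierarchy, because any
ordering would be arbitrary. DMR tiling uses 1 kb windows; only CpAs with
≥5x coverage in *all* samples contribute, so per-tile medians are
comparable across samples. A trailing partial tile is kept, flagged, and
its true length used for densities. A region is retained when qualifying
CpAs are ≥0.5% of all its genomic CpAs (both strands) — "all CpAs" read
as the genomic denominator, the stricter of the two possible readings.
Density profiles emit raw binned values; smoothing is left to plotting.

## Models

*Sample level*: OLS of mean CpA level on log2 expression of DNMT3A,
DNMT3B, DNMT1, OCT4, SOX2, NANOG (normalised to the ES-cell mean),
followed by sequential (type-I) ANOVA. Sequential ANOVA depends on
predictor order; the order is a visible config entry
(`EXPRESSION_PREDICTORS`) with the methyltransferases first, reflecting
their biological priority. *Tile level*: same machinery over 1 kb tiles
(≥2 CpAs covered >5x in all samples). The four base fractions sum to 1,
so T content is dropped from the design to keep it full rank. When
predicting CpA methylation, CpG-density variables (CpG content, CpA–CpG
ratio) are excluded — they would dominate and obscure the rest; when
predicting CpG or CpT, the CpA level enters as a predictor.

*Site level*: the 30 features per CpA (±10 bp windows) are a
reconstruction, since the original feature list is only summarised in the
available text: window base fractions and GC (5), dinucleotide counts
(4), distance to and methylation of the nearest covered CpG plus
windowed CpG-methylation summaries (5), a DNMT3A-preference flanking
motif log-odds score (1), cross-sample conservation/mean/SD (3), focal
and minimum coverage (2), one-hot identities of the −1 and +2 bases (8),
a repeat flag and distance to the nearest CpA (2). Where an original
feature's exact formula is not recoverable the closest standard
definition is used; the correspondence to the original set cannot be
verified feature-by-feature. Labels are `level ≥ 5%` in the focal sample
at ≥15x coverage in all samples; the unmethylated majority is randomly
down-sampled to a balanced set with one seed governing balancing and
folding. AUC is the mean over stratified 10-fold CV; importances come
from a full-data fit: coefficient z-scores for the linear methods (the
logistic information matrix is pseudo-inverted because the one-hot and
composition blocks are collinear by construction) and mean decrease in
Gini rescaled so the maximum is exactly 1 for the 500-tree random forest.

## Synthetic data: what it emulates and what it does not

The generator plants CCGG sites at geometric spacings (default mean
140 bp, putting most fragments in the size window), CG-island-like
regions with strongly elevated CpG density, and per-site truth: CpG from
a two-component mixture (low component supported strictly below 10%,
mean 3%, preferred by island CpGs with probability 0.9; high component
beta around 92%; 30% low genome-wide), CpA i.i.d. exponential, CpT/CpC a
constant noise floor (default 0). The CpA exponential means are the
cell-class presets: 0.037 for pluripotent — chosen once so that the true
exceedance of the 10% methylated threshold, `exp(−0.10/0.037) ≈ 6.7%`,
matches the reported pluripotent %mCpA/CpA regime — 0.012 for
embryoid-body-like partial loss, 0.002 for somatic near-absence. No
generative parameters for these distributions exist in the source beyond
their shapes, so the values are calibration choices, fixed here.

Reads are 36 bp, single-end, directional, emitted at their true positions
with fixed MAPQ (alignment is out of scope); read starts are uniform
within size-selected fragments, counts Poisson per fragment, strands
fair-coin — so a nominal read depth d gives ≈ d/2 informative coverage
per strand-specific site. Each covered cytosine shows the unconverted
base with probability `truth + (1 − truth)(1 − conversion_rate)`.
Deliberately not simulated: sequencing errors, adapters, PCR duplicates,
paired ends, RRBS end-repair fill-in bases (real RRBS fill-in introduces
unmethylated cytosines at fragment ends; omitting it keeps calling
unbiased at the cost of realism), and strand symmetry of any kind. All
randomness flows from one seeded generator per call, recorded in output
headers.

Consequently, passing tests show that the *computational chain* is
correct — calling converges to `truth + (1 − truth)·failure`, cascades
equal their brute-force oracles, statistics equal hand computations, and
planted effects are recovered — not that real RRBS data are free of the
biases the simulator omits (fill-in, duplicates, SNPs, mapping error).

## Numerical choices and degenerate inputs

Thresholds are inclusive unless a rule says otherwise (see filtering).
Zero-mean CV/conservation sites, empty feature classes, empty PFMs and
zero genome-wide contexts are flagged (NaN) rather than silently dropped.
Tile medians with no qualifying CpA are NaN. Degenerate single-class CV
folds trigger a reseeded refold (warned). The exponential fit warns below
100 sites. Problem sizes in tests and the acceptance script (genomes of
8–95 kb, cohorts of 3–12 samples, read depths 25–500x per site) were
chosen as the smallest scales at which each property is statistically
decidable; all scale linearly if larger runs are wanted.

## Known limitations

Single-chromosome genomes in the simulator (the analysis code handles
multi-contig references); no quality- or SNP-aware calling; the
30-feature reconstruction above; no FDR machinery (none is used by the
set definitions implemented here); plotting is out of scope — functions
return tables and arrays meant for downstream plotting.
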