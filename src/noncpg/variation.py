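"""Cross-sample variability statistics for methylation levels.

CpG methylation is highly conserved between pluripotent lines while CpA
methylation is not; this module quantifies that contrast: pairwise Pearson
correlations over consensus sites, per-site coefficients of variation, a
coverage-weighted conservation score with a per-sample coverage cap,
exponential fits to per-site median CpA levels, reduction statistics for
differentiated cells, and the position frequency matrix of flanking
sequence around consistently highly methylated CpAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp
from .calling import SampleTable
from .filtering import (
    ConsensusSet,
    Site,
    build_consensus,
    evident_methylation_partition,
    level_matrix,
    coverage_matrix,
    methylated_set,
)

BASES = ("A", "C", "G", "T")
COVERAGE_CAP = 25


def pairwise_pcc(
    samples: list[SampleTable],
    sites: ConsensusSet | list[Site],
    min_cov: int = 0,
) -> pd.DataFrame:
    """Symmetric matrix of Pearson r between samples over the given sites.

    Levels are compared pairwise-complete: each pair of samples uses the
    sites present (and meeting min_cov) in both. The diagonal is 1; pairs
    where either sample has zero variance get NaN.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    site_list = sites.sites if isinstance(sites, ConsensusSet) else list(sites)
    if not site_list:
        raise ValueError("empty site set")
    ctx = sites.context if isinstance(sites, ConsensusSet) else None
    lv = level_matrix(samples, ctx, min_cov=min_cov)
    lv = lv.loc[lv.index.intersection(pd.MultiIndex.from_tuples(site_list))]
    r = lv.corr(method="pearson", min_periods=2)
    np.fill_diagonal(r.values, 1.0)
    return r


def coefficient_of_variation(
    samples: list[SampleTable],
    sites: list[Site],
    context: str | None = None,
    min_cov: int = 5,
) -> pd.Series:
    """Per-site CV = sample sd (n-1 denominator) / mean across samples.

    Computed listwise: only sites covered >= min_cov in every sample enter.
    Sites with zero mean get NaN (flagged, not dropped).
    """
    lv = level_matrix(samples, context, min_cov=min_cov)
    lv = lv.loc[lv.index.intersection(pd.MultiIndex.from_tuples(list(sites)))]
    lv = lv.dropna(axis=0, how="any")
    mean = lv.mean(axis=1)
    sd = lv.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    cv.name = "cv"
    return cv


@dataclass
class ConservationScore:
    """Coverage-weighted variability of one site across samples.

    Per-sample weights are min(coverage, cap); the score is the weighted
    (population-form) standard deviation over the weighted mean. Undefined
    (NaN score) when the weighted mean is 0.
    """

    weighted_mean: float
    weighted_sd: float
    score: float
    weights: np.ndarray


def conservation_score(
    levels, coverages, cap: int = COVERAGE_CAP
) -> ConservationScore:
    """Score one site from per-sample levels and coverages."""
    x = np.asarray(levels, dtype=float)
    cov = np.asarray(coverages, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 samples covering the site")
    w = np.minimum(cov, cap)
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("all weights zero")
    mu = float((w * x).sum() / wsum)
    sd = float(np.sqrt((w * (x - mu) ** 2).sum() / wsum))
    score = sd / mu if mu > 0 else float("nan")
    return ConservationScore(weighted_mean=mu, weighted_sd=sd, score=score, weights=w)


def conservation_scores(
    samples: list[SampleTable],
    sites: list[Site],
    context: str | None = None,
    min_cov: int = 5,
    cap: int = COVERAGE_CAP,
) -> pd.DataFrame:
    """Vectorised conservation scores for many sites (listwise complete)."""
    lv = level_matrix(samples, context, min_cov=min_cov)
    cv = coverage_matrix(samples, context)
    idx = lv.index.intersection(pd.MultiIndex.from_tuples(list(sites)))
    lv = lv.loc[idx].dropna(axis=0, how="any")
    cv = cv.reindex(lv.index)[lv.columns]
    w = np.minimum(cv.to_numpy(float), cap)
    x = lv.to_numpy(float)
    wsum = w.sum(axis=1)
    mu = (w * x).sum(axis=1) / wsum
    sd = np.sqrt((w * (x - mu[:, None]) ** 2).sum(axis=1) / wsum)
    score = np.where(mu > 0, sd / np.where(mu > 0, mu, 1.0), np.nan)
    return pd.DataFrame(
        {"weighted_mean": mu, "weighted_sd": sd, "score": score}, index=lv.index
    )


@dataclass
class ExponentialFit:
    mean: float      # fitted exponential mean (1/rate)
    rate: float
    ks_stat: float
    ks_p: float
    n: int


def fit_exponential(values) -> ExponentialFit:
    """Closed-form exponential MLE (rate = 1/mean) on positive values, with KS GOF."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) == 0:
        raise ValueError("no positive values to fit")
    mean = float(v.mean())
    ks = stats.kstest(v, "expon", args=(0, mean))
    return ExponentialFit(
        mean=mean, rate=1.0 / mean, ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue), n=len(v),
    )


def fit_exponential_medians(
    samples: list[SampleTable],
    context: str = "CpA",
    median_threshold: float = 0.001,
    min_cov: int = 5,
    min_sites: int = 100,
) -> ExponentialFit:
    """Fit an exponential to per-site across-sample median levels.

    Operates on the evident-methylation partition (median >= 0.1% by
    default). CpA medians are well described by an exponential; bimodal CpG
    medians are not, which the KS distance reports.
    """
    sites = evident_methylation_partition(
        samples, context, median_threshold=median_threshold, min_cov=min_cov
    )
    lv = level_matrix(samples, context, min_cov=min_cov)
    lv = lv.loc[lv.index.intersection(pd.MultiIndex.from_tuples(sites))]
    med = lv.median(axis=1, skipna=True)
    if len(med) < min_sites:
        import warnings

        warnings.warn(f"only {len(med)} sites for exponential fit", stacklevel=2)
    return fit_exponential(med.to_numpy())


def reduction_stats(
    reference: list[SampleTable],
    other: list[SampleTable],
    context: str,
    min_cov: int = 5,
    threshold: float = 0.05,
    strict: bool = False,
    consensus: ConsensusSet | None = None,
) -> float:
    """Percent reduction in the mean number of methylated sites vs reference.

    Methylated per the >=5% counting rule by default. If a consensus set is
    given, counting is restricted to it. Returns
    100 * (1 - mean count in other / mean count in reference).
    """
    restrict = set(consensus.sites) if consensus is not None else None

    def mean_count(group: list[SampleTable]) -> float:
        counts = []
        for s in group:
            m = methylated_set(s, context, min_cov=min_cov, threshold=threshold,
                               strict=strict)
            counts.append(len(m & restrict) if restrict is not None else len(m))
        return float(np.mean(counts))

    ref = mean_count(reference)
    if ref == 0:
        raise ValueError("reference has no methylated sites: reduction undefined")
    return 100.0 * (1.0 - mean_count(other) / ref)


@dataclass
class PositionFrequencyMatrix:
    """Base frequencies at offsets around the C of qualifying CpAs.

    Offset 0 is the C and offset +1 the A (both trivially fixed); flanking
    columns hold the empirical base composition on the CpA's own strand.
    """

    matrix: pd.DataFrame  # index: offsets, columns: A/C/G/T
    n_sites: int

    def to_meme(self, name: str = "mCpA_context") -> str:
        lines = [
            "MEME version 4", "", "ALPHABET= ACGT", "",
            "strands: +", "",
            "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {len(self.matrix)} "
            f"nsites= {self.n_sites} E= 0",
        ]
        for _, row in self.matrix.iterrows():
            lines.append("  ".join(f"{row[b]:.6f}" for b in BASES))
        return "\n".join(lines) + "\n"


def motif_matrix(
    samples: list[SampleTable],
    genome,
    min_cov: int = 10,
    min_sample_frac: float = 0.8,
    min_mean_level: float = 0.15,
    flank: int = 5,
) -> PositionFrequencyMatrix:
    """Sequence context of consistently highly methylated CpAs.

    Qualifying CpAs have >= min_cov coverage in >= min_sample_frac of the
    samples and mean level >= min_mean_level over all samples. Flanks are
    extracted on the CpA's own strand (minus-strand sites are
    reverse-complemented) so offset 0 is always C and offset +1 always A.
    """
    from .calling import load_genome

    seqs = load_genome(genome)
    cons = build_consensus(samples, "CpA", min_cov=min_cov,
                           min_sample_frac=min_sample_frac)
    lv = level_matrix(samples, "CpA", min_cov=min_cov)
    lv = lv.loc[lv.index.intersection(pd.MultiIndex.from_tuples(cons.sites))]
    mean_lv = lv.mean(axis=1, skipna=True)
    qual = mean_lv[mean_lv >= min_mean_level].index

    offsets = list(range(-flank, flank + 2))  # through the A at +1
    counts = pd.DataFrame(0, index=offsets, columns=list(BASES))
    n_sites = 0
    for chrom, pos0, strand in qual:
        seq = seqs[chrom]
        if strand == "+":
            s, e = pos0 - flank, pos0 + flank + 2
            if s < 0 or e > len(seq):
                continue
            window = seq[s:e]
        else:
            s, e = pos0 - flank - 1, pos0 + flank + 1
            if s < 0 or e > len(seq):
                continue
            window = revcomp(seq[s:e])
        n_sites += 1
        for off, base in zip(offsets, window):
            if base in BASES:
                counts.loc[off, base] += 1
    if n_sites == 0:
        return PositionFrequencyMatrix(
            matrix=counts.astype(float), n_sites=0
        )
    freq = counts.div(counts.sum(axis=1), axis=0)
    return PositionFrequencyMatrix(matrix=freq, n_sites=n_sites)
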