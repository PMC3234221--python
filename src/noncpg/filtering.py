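"""Coverage and threshold cascades for cross-sample site selection.

RRBS coverage varies between samples, so every cross-sample statistic in
this package operates on explicitly defined site sets: consensus sets
(minimum coverage in a minimum fraction of samples), methylated-site sets
(coverage plus a context-specific level threshold), and the minimal
"evident methylation" partition (across-sample median level above 0.1%)
that keeps the overwhelmingly unmethylated background from dominating
distribution statistics.

Every named threshold rule records its comparison direction so boundary
conventions are auditable: all rules are inclusive (>=) except the non-CpG
whole-methylome comparison rule, which is stated as "above 5%" and is
therefore strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .calling import SampleTable

Site = tuple[str, int, str]  # (chrom, pos0, strand)


@dataclass(frozen=True)
class ThresholdRule:
    """A methylated-site definition: coverage cutoff + level threshold."""

    min_cov: int
    threshold: float
    strict: bool = False  # True: level > threshold; False: level >= threshold

    def applies(self, level) -> np.ndarray:
        level = np.asarray(level, dtype=float)
        return level > self.threshold if self.strict else level >= self.threshold


#: Named rule sets used throughout the analyses. Keys: context class ->
#: rule. "table1" is the >=10% summary-statistics rule (all contexts);
#: "wm_overlap" is the whole-methylome comparison rule (30% CpG inclusive,
#: 5% non-CpG strict); "differentiated" is the >=5% methylated-CpA counting
#: rule used for differentiated-cell comparisons.
THRESHOLD_RULES: dict[str, dict[str, ThresholdRule]] = {
    "table1": {ctx: ThresholdRule(5, 0.10) for ctx in ("CpG", "CpA", "CpT", "CpC")},
    "wm_overlap": {
        "CpG": ThresholdRule(5, 0.30),
        "CpA": ThresholdRule(5, 0.05, strict=True),
        "CpT": ThresholdRule(5, 0.05, strict=True),
        "CpC": ThresholdRule(5, 0.05, strict=True),
    },
    "differentiated": {
        ctx: ThresholdRule(5, 0.05) for ctx in ("CpG", "CpA", "CpT", "CpC")
    },
}

#: Named consensus rules: (min_cov, min_sample_frac).
CONSENSUS_RULES = {
    "consensus_plu": (5, 0.8),
    "consensus_diff": (5, 0.7),
    "consensus_2x": (2, 0.8),
    "motif": (10, 0.8),
}


@dataclass
class ConsensusSet:
    context: str
    sites: list[Site]
    rule: tuple[int, float]  # (min_cov, min_sample_frac)

    def __len__(self) -> int:
        return len(self.sites)


def _context_df(table: SampleTable, context: str | None) -> pd.DataFrame:
    df = table.df
    if context is None:
        return df
    if context == "non-CpG":
        return df[df["context"] != "CpG"]
    return df[df["context"] == context]


def coverage_matrix(
    samples: list[SampleTable], context: str | None = None
) -> pd.DataFrame:
    """Sites x samples total read counts (0 where a site is absent)."""
    cols = {}
    for s in samples:
        df = _context_df(s, context)
        cols[s.sample_id] = df.set_index(["chrom", "pos0", "strand"])["total_count"]
    out = pd.DataFrame(cols).fillna(0).astype(int)
    return out.sort_index()


def level_matrix(
    samples: list[SampleTable],
    context: str | None = None,
    min_cov: int = 0,
) -> pd.DataFrame:
    """Sites x samples methylation levels, NaN where coverage < min_cov."""
    cols = {}
    for s in samples:
        df = _context_df(s, context)
        if min_cov > 0:
            df = df[df["total_count"] >= min_cov]
        cols[s.sample_id] = df.set_index(["chrom", "pos0", "strand"])["level"]
    return pd.DataFrame(cols).sort_index()


def build_consensus(
    samples: list[SampleTable],
    context: str,
    min_cov: int = 5,
    min_sample_frac: float = 0.8,
) -> ConsensusSet:
    """Sites covered >= min_cov in at least min_sample_frac of the samples.

    The fraction comparison is inclusive (4 of 5 samples meets 0.8). Sites
    are returned in genome order.
    """
    if len(samples) < 2:
        raise ValueError("consensus requires >= 2 samples")
    if not 0 < min_sample_frac <= 1:
        raise ValueError("min_sample_frac must be in (0, 1]")
    cov = coverage_matrix(samples, context)
    frac = (cov >= min_cov).sum(axis=1) / len(samples)
    sites = [tuple(ix) for ix in cov.index[frac >= min_sample_frac]]
    return ConsensusSet(context=context, sites=sites, rule=(min_cov, min_sample_frac))


def methylated_set(
    table: SampleTable,
    context: str,
    min_cov: int = 5,
    threshold: float = 0.10,
    strict: bool = False,
) -> set[Site]:
    """Sites with total_count >= min_cov whose level meets the threshold."""
    rule = ThresholdRule(min_cov, threshold, strict)
    df = _context_df(table, context)
    df = df[df["total_count"] >= rule.min_cov]
    keep = rule.applies(df["level"].to_numpy())
    return {
        tuple(r)
        for r in df.loc[keep, ["chrom", "pos0", "strand"]].itertuples(index=False)
    }


@dataclass
class OverlapResult:
    intersection: int
    jaccard: float
    fisher_p: float
    table: np.ndarray  # 2x2 contingency over the universe


def overlap(
    set_a: set[Site], set_b: set[Site], universe: set[Site]
) -> OverlapResult:
    """Overlap of two site sets within a joint-coverage universe.

    Only sites in the universe (e.g. covered >= 5x in both samples) are
    considered. The Fisher exact test (two-sided) is computed on the 2x2
    membership table over the universe.
    """
    if not universe:
        raise ValueError("empty universe: overlap undefined")
    a = set_a & universe
    b = set_b & universe
    inter = len(a & b)
    union = len(a | b)
    tab = np.array(
        [
            [inter, len(a - b)],
            [len(b - a), len(universe) - union],
        ]
    )
    _, p = fisher_exact(tab, alternative="two-sided")
    return OverlapResult(
        intersection=inter,
        jaccard=inter / union if union else float("nan"),
        fisher_p=float(p),
        table=tab,
    )


def evident_methylation_partition(
    samples: list[SampleTable],
    context: str,
    median_threshold: float = 0.001,
    min_cov: int = 5,
) -> list[Site]:
    """Sites whose across-sample median level is >= the minimal threshold.

    The median is taken over the samples in which the site meets the
    coverage rule; sites covered in no sample are dropped. The default 0.1%
    median threshold separates cytosines with any evidence of methylation
    from the unmethylated bulk.
    """
    if not samples:
        raise ValueError("need >= 1 sample")
    lv = level_matrix(samples, context, min_cov=min_cov)
    med = lv.median(axis=1, skipna=True)
    keep = med >= median_threshold
    return [tuple(ix) for ix in lv.index[keep.fillna(False)]]
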