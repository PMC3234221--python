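"""Genomic-feature aggregation and 1 kb tiling of candidate DMRs.

Methylation levels are summarised over feature classes (promoters, CG
islands, high/low-CpG promoters, exons, introns, repeats, ...) and over
megabase-scale candidate differentially methylated regions tiled into 1 kb
windows. Promoters span TSS-5 kb to TSS+1 kb oriented by gene strand; a
high-CpG promoter (HCP) overlaps a CG island by at least one base, a
low-CpG promoter (LCP) does not. All intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import SampleTable, load_genome
from .filtering import level_matrix
from ._seq import cytosine_table

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class FeatureClass:
    """A named set of BED-style intervals (0-based half-open)."""

    label: str
    intervals: list[Interval] = field(default_factory=list)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(pos), dtype=bool)
        for s, e in self.intervals:
            hit |= (pos >= s) & (pos < e)
        return hit

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "FeatureClass":
        ivals = []
        name = label
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                ivals.append((int(parts[1]), int(parts[2])))
                if name is None and len(parts) > 3:
                    name = parts[3]
        return cls(label=name or "feature", intervals=ivals)


def make_promoters(
    genes: list[tuple[str, int, str]], upstream: int = 5000, downstream: int = 1000
) -> FeatureClass:
    """Promoter windows -5 kb..+1 kb around each TSS, oriented by gene strand.

    ``genes`` is a list of (name, tss, strand). For a plus-strand gene the
    window is [tss - upstream, tss + downstream); for a minus-strand gene it
    is mirrored around the TSS.
    """
    ivals = []
    for _, tss, strand in genes:
        if strand == "+":
            ivals.append((max(0, tss - upstream), tss + downstream))
        else:
            ivals.append((max(0, tss - downstream + 1), tss + upstream + 1))
    return FeatureClass(label="promoter", intervals=ivals)


def classify_promoters(
    promoters: FeatureClass, islands: list[Interval]
) -> tuple[FeatureClass, FeatureClass]:
    """Split promoters into HCP (overlaps a CG island) and LCP (does not)."""
    hcp, lcp = [], []
    for s, e in promoters.intervals:
        if any(s < ie and isl_s < e for isl_s, ie in islands):
            hcp.append((s, e))
        else:
            lcp.append((s, e))
    return FeatureClass("HCP", hcp), FeatureClass("LCP", lcp)


def aggregate_by_feature(
    table: SampleTable,
    features: list[FeatureClass],
    context: str | None = None,
    min_cov: int = 5,
) -> pd.DataFrame:
    """Per-class distribution summary of methylation levels.

    Each qualifying cytosine is assigned to every class whose intervals
    contain it (classes may overlap; there is no precedence). Returns a
    DataFrame indexed by class label with n, mean and quartiles; empty
    classes get NaN summaries.
    """
    df = table.df[table.df["total_count"] >= min_cov]
    if context is not None:
        df = df[df["context"] == context]
    pos = df["pos0"].to_numpy()
    levels = df["level"].to_numpy()
    rows = []
    for fc in features:
        hit = fc.contains(pos)
        x = levels[hit]
        if len(x) == 0:
            rows.append({"label": fc.label, "n": 0, "mean": np.nan, "q25": np.nan,
                         "median": np.nan, "q75": np.nan})
        else:
            rows.append({
                "label": fc.label, "n": int(len(x)), "mean": float(np.mean(x)),
                "q25": float(np.percentile(x, 25)),
                "median": float(np.median(x)),
                "q75": float(np.percentile(x, 75)),
            })
    return pd.DataFrame(rows).set_index("label")


@dataclass
class TileProfile:
    """1 kb tiling of one region with per-sample tile medians.

    ``medians`` is a tiles x samples DataFrame of median CpA levels over the
    qualifying CpAs in each tile (NaN where a tile has none). A region is
    retained when the fraction of its genomic CpAs that qualify (coverage
    >= min_cov in all samples) is at least ``min_covered_frac``.
    """

    region: Interval
    tiles: list[Interval]
    medians: pd.DataFrame
    cpg_density: np.ndarray
    cpa_density: np.ndarray
    covered_frac: float
    retained: bool
    partial_last_tile: bool


def _dinuc_positions(seq: str, chrom: str, context: str) -> np.ndarray:
    ct = cytosine_table(seq, chrom)
    return ct.loc[ct["context"] == context, "pos0"].to_numpy()


def tile_dmr(
    region: Interval,
    samples: list[SampleTable],
    genome,
    tile_bp: int = 1000,
    min_cov: int = 5,
    min_covered_frac: float = 0.005,
    chrom: str | None = None,
) -> TileProfile:
    """Tile a region into 1 kb windows of per-sample median CpA levels.

    Only CpAs with >= min_cov coverage in *all* samples contribute (so tile
    medians are comparable across samples). A trailing partial tile is kept
    with its true length. The region is retained when at least
    ``min_covered_frac`` of all its genomic CpAs (both strands) qualify.
    """
    start, end = region
    if end - start < tile_bp:
        raise ValueError("region shorter than one tile")
    seqs = load_genome(genome)
    if chrom is None:
        chrom = next(iter(seqs))
    seq = seqs[chrom]

    tiles = []
    s = start
    while s < end:
        tiles.append((s, min(s + tile_bp, end)))
        s += tile_bp
    partial = tiles[-1][1] - tiles[-1][0] < tile_bp

    lv = level_matrix(samples, "CpA", min_cov=min_cov).dropna(axis=0, how="any")
    lv = lv[lv.index.get_level_values("chrom") == chrom]
    pos = lv.index.get_level_values("pos0").to_numpy()
    in_region = (pos >= start) & (pos < end)
    lv_r, pos_r = lv[in_region], pos[in_region]

    ct = cytosine_table(seq, chrom)
    cpa_all = ct.loc[ct["context"] == "CpA", "pos0"].to_numpy()
    cpg_all = ct.loc[ct["context"] == "CpG", "pos0"].to_numpy()
    n_cpa_region = int(((cpa_all >= start) & (cpa_all < end)).sum())
    covered_frac = len(lv_r) / n_cpa_region if n_cpa_region else 0.0

    med_rows, cpg_d, cpa_d = [], [], []
    for ts, te in tiles:
        mask = (pos_r >= ts) & (pos_r < te)
        sub = lv_r[mask]
        med_rows.append(sub.median(axis=0) if len(sub) else
                        pd.Series(np.nan, index=lv.columns))
        tl = te - ts
        cpg_d.append(((cpg_all >= ts) & (cpg_all < te)).sum() / tl)
        cpa_d.append(((cpa_all >= ts) & (cpa_all < te)).sum() / tl)
    medians = pd.DataFrame(
        med_rows, index=pd.MultiIndex.from_tuples(tiles, names=["tile_start", "tile_end"])
    )
    return TileProfile(
        region=region,
        tiles=tiles,
        medians=medians,
        cpg_density=np.asarray(cpg_d),
        cpa_density=np.asarray(cpa_d),
        covered_frac=covered_frac,
        retained=covered_frac >= min_covered_frac,
        partial_last_tile=partial,
    )


def cpg_density_profile(
    regions: list[Interval],
    genome,
    n_bins: int = 30,
    flank_bp: int = 30000,
    flank_bin: int = 1000,
    chrom: str | None = None,
) -> dict[str, np.ndarray]:
    """Average CpG-density profile over regions, with fixed-width flank bins.

    Each region is divided into ``n_bins`` equally long intervals and the
    CpG dinucleotide density (count / bin length) of each computed; matching
    bins are averaged across regions. Flanks of ``flank_bp`` on each side
    are binned at a fixed ``flank_bin`` width. Regions shorter than
    ``n_bins`` bases are rejected and logged. The profile is computed on
    plus-strand CG occurrences and is strand-symmetric by construction.
    """
    seqs = load_genome(genome)
    if chrom is None:
        chrom = next(iter(seqs))
    seq = seqs[chrom]
    arr_cg = np.array(
        [1 if seq[i : i + 2] == "CG" else 0 for i in range(len(seq) - 1)], dtype=float
    )
    cum = np.concatenate([[0.0], np.cumsum(arr_cg)])

    def density(s: int, e: int) -> float:
        s, e = max(0, s), min(len(seq) - 1, e)
        if e <= s:
            return np.nan
        return (cum[e] - cum[s]) / (e - s)

    n_flank = flank_bp // flank_bin
    body = np.zeros((0, n_bins))
    up = np.zeros((0, n_flank))
    down = np.zeros((0, n_flank))
    for start, end in regions:
        if end - start < n_bins:
            logger.warning("region (%d, %d) shorter than %d bins; skipped",
                           start, end, n_bins)
            continue
        edges = np.linspace(start, end, n_bins + 1).astype(int)
        body = np.vstack([body, [density(edges[i], edges[i + 1])
                                 for i in range(n_bins)]])
        up = np.vstack([up, [density(start - (i + 1) * flank_bin,
                                     start - i * flank_bin)
                             for i in reversed(range(n_flank))]])
        down = np.vstack([down, [density(end + i * flank_bin,
                                         end + (i + 1) * flank_bin)
                                 for i in range(n_flank)]])
    if body.shape[0] == 0:
        raise ValueError("no region long enough to profile")
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            # flank bins falling entirely off the chromosome are NaN by design
            warnings.simplefilter("ignore", RuntimeWarning)
            return {
                "body": np.nanmean(body, axis=0),
                "upstream": np.nanmean(up, axis=0),
                "downstream": np.nanmean(down, axis=0),
            }
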