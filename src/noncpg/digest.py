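"""In-silico MspI digestion, fragment size selection, and coverage statistics.

RRBS enriches the genome by cutting with the methylation-insensitive enzyme
MspI (C^CGG) and sequencing fragments in a size window (40-260 bp by
default). Which cytosine dinucleotides fall inside selected fragments — and
how their frequencies compare to the whole genome — determines what the
protocol can see: CpGs are strongly enriched by design, while the non-CpG
contexts are covered at a small but representative rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import CONTEXTS, cytosine_table
from .synthetic import SyntheticGenome

DEFAULT_SIZE_WINDOW = (40, 260)


@dataclass
class FragmentSet:
    """Digestion fragments tiling one chromosome, 0-based half-open."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    selected: np.ndarray  # bool per fragment
    size_window: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.starts)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    def selected_intervals(self) -> list[tuple[int, int]]:
        return [
            (int(s), int(e))
            for s, e, keep in zip(self.starts, self.ends, self.selected)
            if keep
        ]

    def to_bed(self, path) -> None:
        """BED with the selected flag in the score column (1 selected, 0 not)."""
        with open(path, "w") as fh:
            for i, (s, e, keep) in enumerate(
                zip(self.starts, self.ends, self.selected)
            ):
                fh.write(f"{self.chrom}\t{s}\t{e}\tfrag{i}\t{int(keep)}\t.\n")


def _find_all(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) match start positions of motif in seq."""
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def _genome_seq(genome) -> tuple[str, str]:
    if isinstance(genome, SyntheticGenome):
        return genome.name, genome.sequence
    if isinstance(genome, tuple):
        return genome
    return "chr1", str(genome)


def digest(genome, site: str = "CCGG", cut_offset: int = 1) -> FragmentSet:
    """Cut at every motif occurrence (offset from match start) and return fragments.

    MspI cuts C^CGG, i.e. one base into the motif; fragment boundaries are the
    cut positions plus the leading and trailing remainder intervals.
    Overlapping motif occurrences each contribute a cut.
    """
    chrom, seq = _genome_seq(genome)
    n = len(seq)
    if n == 0:
        return FragmentSet(
            chrom, np.array([], int), np.array([], int), np.array([], bool)
        )
    cuts = sorted({m + cut_offset for m in _find_all(seq, site) if 0 < m + cut_offset < n})
    bounds = np.array([0] + cuts + [n], dtype=int)
    starts, ends = bounds[:-1], bounds[1:]
    return FragmentSet(
        chrom=chrom,
        starts=starts,
        ends=ends,
        selected=np.ones(len(starts), dtype=bool),
    )


def size_select(
    frags: FragmentSet,
    min_bp: int = DEFAULT_SIZE_WINDOW[0],
    max_bp: int = DEFAULT_SIZE_WINDOW[1],
) -> FragmentSet:
    """Flag fragments whose length is within [min_bp, max_bp], inclusive both ends."""
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    lengths = frags.lengths()
    selected = (lengths >= min_bp) & (lengths <= max_bp)
    return FragmentSet(
        chrom=frags.chrom,
        starts=frags.starts.copy(),
        ends=frags.ends.copy(),
        selected=selected,
        size_window=(min_bp, max_bp),
    )


def dinucleotide_census(genome, frags: FragmentSet) -> pd.DataFrame:
    """Per-context counts of cytosine dinucleotides genome-wide and in selected fragments.

    Both strands are counted as distinct sites. A dinucleotide belongs to a
    fragment only if both of its bases lie inside the fragment interval, so
    sites straddling a cut boundary are not covered. Returns a DataFrame
    indexed by context with columns (covered, total, fraction).
    """
    chrom, seq = _genome_seq(genome)
    sites = cytosine_table(seq, chrom)
    pos = sites["pos0"].to_numpy()
    is_plus = sites["strand"].to_numpy() == "+"
    # second base of the dinucleotide: pos+1 on plus, pos-1 on minus
    other = np.where(is_plus, pos + 1, pos - 1)

    covered = np.zeros(len(sites), dtype=bool)
    if len(frags) > 0:
        idx = np.searchsorted(frags.starts, np.minimum(pos, other), side="right") - 1
        idx = np.clip(idx, 0, len(frags) - 1)
        inside = (
            (np.minimum(pos, other) >= frags.starts[idx])
            & (np.maximum(pos, other) < frags.ends[idx])
        )
        covered = inside & frags.selected[idx]

    rows = []
    for ctx in CONTEXTS:
        mask = (sites["context"] == ctx).to_numpy()
        total = int(mask.sum())
        cov = int((mask & covered).sum())
        rows.append(
            {
                "context": ctx,
                "covered": cov,
                "total": total,
                "fraction": cov / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("context")


def enrichment(census: pd.DataFrame) -> pd.Series:
    """Per-context frequency among covered dinucleotides relative to genome-wide.

    A ratio of 1 means the size-selected library sees that context at its
    genomic frequency; >1 means enrichment. Contexts absent genome-wide get NaN.
    """
    cov_all = census["covered"].sum()
    tot_all = census["total"].sum()
    if cov_all == 0 or tot_all == 0:
        return pd.Series(np.nan, index=census.index, name="enrichment")
    ratio = (census["covered"] / cov_all) / (census["total"] / tot_all)
    ratio[census["total"] == 0] = np.nan
    ratio.name = "enrichment"
    return ratio
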