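"""Per-cytosine methylation calling from bisulfite alignments.

The methylation level of a strand-specific cytosine is the fraction of
reads showing an unconverted cytosine over the total number of reads
covering it. Reads are directional: a forward alignment reports plus-strand
cytosines (read base C = unconverted, T = converted) and a reverse alignment
reports minus-strand cytosines at reference G positions (read base G =
unconverted, A = converted, in plus-strand orientation). Any other read base
— sequencing N's or mismatches — contributes to neither count. The context
of every cytosine is taken from the reference, never from the read.

The bisulfite conversion rate of a sample is estimated two ways, as in
standard RRBS quality control: from the global mean CpC methylation level
(CpC methylation is essentially conversion noise) and from the mean
methylation of high-CpG-density island promoters (normally unmethylated).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from ._seq import C, G, CONTEXTS, cytosine_table, seq_array
from .synthetic import SyntheticGenome

_C, _T, _G, _A = (ord(b) for b in "CTGA")


@dataclass
class CytosineRecord:
    """One strand-specific cytosine with its read counts."""

    chrom: str
    pos0: int
    strand: str
    context: str
    meth_count: int
    total_count: int

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count if self.total_count else float("nan")


class ConversionEstimate(NamedTuple):
    global_cpc: float
    island_promoter: float


@dataclass
class SampleTable:
    """Per-sample table of covered cytosines.

    ``df`` columns: chrom, pos0, strand, context, meth_count, total_count,
    level — one row per (chrom, pos0, strand).
    """

    sample_id: str
    df: pd.DataFrame
    conversion_estimates: ConversionEstimate | None = None

    def __len__(self) -> int:
        return len(self.df)

    def record(self, chrom: str, pos0: int, strand: str) -> CytosineRecord | None:
        m = self.df[
            (self.df["chrom"] == chrom)
            & (self.df["pos0"] == pos0)
            & (self.df["strand"] == strand)
        ]
        if m.empty:
            return None
        r = m.iloc[0]
        return CytosineRecord(
            r["chrom"], int(r["pos0"]), r["strand"], r["context"],
            int(r["meth_count"]), int(r["total_count"]),
        )

    def to_tsv(self, path) -> None:
        """CX-report-style per-cytosine table."""
        self.df.to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path, context: str | None = None) -> None:
        df = self.df if context is None else self.df[self.df["context"] == context]
        with open(path, "w") as fh:
            for chrom, pos0, level in df[["chrom", "pos0", "level"]].itertuples(
                index=False
            ):
                fh.write(f"{chrom}\t{pos0}\t{pos0 + 1}\t{level:.6g}\n")


def load_genome(genome) -> dict[str, str]:
    """Accept a SyntheticGenome, dict of sequences, or FASTA path."""
    if isinstance(genome, SyntheticGenome):
        return {genome.name: genome.sequence}
    if isinstance(genome, dict):
        return genome
    path = Path(genome)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _iter_alignments(alignments):
    """Yield (chrom, start, is_reverse, query bytes, cigar-is-simple, segment)."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            for a in fh:
                if a.is_unmapped:
                    continue
                yield a.reference_name, a.reference_start, a.is_reverse, a
    else:  # an in-memory ReadSet from the simulator
        for r in alignments.reads:
            yield r.chrom, r.start, r.strand == "-", r


def call(alignments, genome, sample_id: str = "sample") -> SampleTable:
    """Call per-cytosine methylation from a SAM file or simulated ReadSet.

    Unknown contigs raise; reads running past the contig end are skipped.
    Indel-containing alignments fall back to per-base aligned pairs so that
    inserted/deleted positions are ignored at the affected sites.
    """
    seqs = load_genome(genome)
    ref_arrays = {c: seq_array(s) for c, s in seqs.items()}
    meth = {c: {"+": np.zeros(len(s), np.int64), "-": np.zeros(len(s), np.int64)} for c, s in seqs.items()}
    tot = {c: {"+": np.zeros(len(s), np.int64), "-": np.zeros(len(s), np.int64)} for c, s in seqs.items()}

    for chrom, start, is_rev, rec in _iter_alignments(alignments):
        if chrom not in ref_arrays:
            raise KeyError(f"alignment references unknown contig {chrom!r}")
        ref = ref_arrays[chrom]
        if isinstance(rec, pysam.AlignedSegment):
            if rec.cigartuples and any(op != 0 for op, _ in rec.cigartuples):
                _call_gapped(rec, ref, meth[chrom], tot[chrom], is_rev)
                continue
            q = np.frombuffer(rec.query_sequence.encode("ascii"), np.uint8)
        else:
            q = np.frombuffer(rec.seq.encode("ascii"), np.uint8)
        end = start + len(q)
        if end > len(ref):
            continue  # read beyond contig end: skip
        r = ref[start:end]
        if not is_rev:
            cs = r == C
            m = cs & (q == _C)
            t = m | (cs & (q == _T))
            meth[chrom]["+"][start:end] += m
            tot[chrom]["+"][start:end] += t
        else:
            gs = r == G
            m = gs & (q == _G)
            t = m | (gs & (q == _A))
            meth[chrom]["-"][start:end] += m
            tot[chrom]["-"][start:end] += t

    frames = []
    for chrom, seq in seqs.items():
        sites = cytosine_table(seq, chrom)
        pos = sites["pos0"].to_numpy()
        strand = sites["strand"].to_numpy()
        t = np.where(strand == "+", tot[chrom]["+"][pos], tot[chrom]["-"][pos])
        m = np.where(strand == "+", meth[chrom]["+"][pos], meth[chrom]["-"][pos])
        keep = t > 0
        frames.append(
            sites[keep].assign(meth_count=m[keep], total_count=t[keep])
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos0", "strand", "context", "meth_count", "total_count"]
    )
    df["level"] = df["meth_count"] / df["total_count"]
    return SampleTable(sample_id=sample_id, df=df)


def _call_gapped(rec, ref, meth, tot, is_rev) -> None:
    qseq = rec.query_sequence
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        if rpos >= len(ref):
            continue
        rb, qb = ref[rpos], ord(qseq[qpos])
        if not is_rev and rb == C:
            if qb == _C:
                meth["+"][rpos] += 1
                tot["+"][rpos] += 1
            elif qb == _T:
                tot["+"][rpos] += 1
        elif is_rev and rb == G:
            if qb == _G:
                meth["-"][rpos] += 1
                tot["-"][rpos] += 1
            elif qb == _A:
                tot["-"][rpos] += 1


def estimate_conversion(
    table: SampleTable, hcp_promoters: list[tuple[int, int]] | None = None
) -> ConversionEstimate:
    """Bisulfite conversion rate from global CpC levels and island promoters.

    ``global_cpc`` = 1 - mean level over all CpC records. ``island_promoter``
    = 1 - mean level over all cytosines inside the given promoter intervals
    (NaN if no intervals are supplied). Raises if the table has no CpC records.
    """
    cpc = table.df[table.df["context"] == "CpC"]
    if cpc.empty:
        raise ValueError("no CpC records: conversion rate undefined")
    global_cpc = 1.0 - float(cpc["level"].mean())

    island = float("nan")
    if hcp_promoters:
        pos = table.df["pos0"].to_numpy()
        inside = np.zeros(len(table.df), dtype=bool)
        for s, e in hcp_promoters:
            inside |= (pos >= s) & (pos < e)
        if inside.any():
            island = 1.0 - float(table.df.loc[inside, "level"].mean())
    est = ConversionEstimate(global_cpc=global_cpc, island_promoter=island)
    table.conversion_estimates = est
    return est


def context_summary(
    table: SampleTable, min_cov: int = 5, meth_threshold: float = 0.10
) -> pd.DataFrame:
    """Per-context methylated fractions at a coverage cutoff.

    A site enters the denominator when total_count >= min_cov and counts as
    methylated when level >= meth_threshold (inclusive). Returns, per
    context: n_covered, n_methylated, pct_methylated (%mCN/CN) and
    share_of_methylated (that context's share among all methylated
    cytosines, summing to 100%).
    """
    df = table.df[table.df["total_count"] >= min_cov]
    rows = []
    for ctx in CONTEXTS:
        sub = df[df["context"] == ctx]
        n_cov = len(sub)
        n_meth = int((sub["level"] >= meth_threshold).sum())
        rows.append({"context": ctx, "n_covered": n_cov, "n_methylated": n_meth})
    out = pd.DataFrame(rows).set_index("context")
    out["pct_methylated"] = 100.0 * out["n_methylated"] / out["n_covered"].where(
        out["n_covered"] > 0
    )
    total_meth = out["n_methylated"].sum()
    out["share_of_methylated"] = (
        100.0 * out["n_methylated"] / total_meth if total_meth else np.nan
    )
    return out
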