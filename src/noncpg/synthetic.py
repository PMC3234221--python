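"""Synthetic RRBS data with known ground truth.

Emulates the essential structure of a bisulfite-sequencing study of non-CpG
methylation in pluripotent versus differentiated human cells: a small genome
with MspI (CCGG) sites and CG-island-like regions, per-cytosine true
methylation levels (bimodal CpG, exponentially distributed CpA, near-zero
CpT/CpC), and 36 bp directional bisulfite reads with a tunable conversion
failure rate. Reads are emitted at their true positions, so every downstream
stage can be validated against the generative truth without any alignment
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from ._seq import C, G, cytosine_table, seq_array

#: Study-condition presets: exponential mean of true CpA levels per cell
#: class. The pluripotent value puts exp(-0.10/0.037) ~ 6.7% of CpAs above
#: the 10% methylated-site threshold, the regime reported for human ES cells;
#: embryoid-body and somatic presets represent partial and near-complete loss.
CPA_MEAN_PRESETS = {
    "pluripotent": 0.037,
    "embryoid_body": 0.012,
    "somatic": 0.002,
}

DEFAULT_READ_LEN = 36  # standard single-end RRBS read length
DEFAULT_CONVERSION_RATE = 0.99


@dataclass
class SyntheticGenome:
    """A small A/C/G/T genome with planted CCGG sites and CG-island-like regions."""

    name: str
    sequence: str
    features: list[tuple[str, int, int]] = field(default_factory=list)
    islands: list[tuple[int, int]] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}")
            if self.seed is not None:
                fh.write(f" seed={self.seed}")
            fh.write("\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")


@dataclass
class MethylationTruth:
    """Per-site true methylation probabilities for one genome.

    ``table`` has one row per strand-specific cytosine with columns
    (chrom, pos0, strand, context, true_level).
    """

    table: pd.DataFrame
    seed: int | None = None

    @property
    def entries(self) -> dict:
        return {
            (p, s): (c, l)
            for p, s, c, l in self.table[
                ["pos0", "strand", "context", "true_level"]
            ].itertuples(index=False)
        }

    def level_arrays(self, genome_len: int) -> tuple[np.ndarray, np.ndarray]:
        """(plus, minus) per-position true levels, NaN where there is no cytosine."""
        plus = np.full(genome_len, np.nan)
        minus = np.full(genome_len, np.nan)
        t = self.table
        is_plus = t["strand"].to_numpy() == "+"
        plus[t["pos0"].to_numpy()[is_plus]] = t["true_level"].to_numpy()[is_plus]
        minus[t["pos0"].to_numpy()[~is_plus]] = t["true_level"].to_numpy()[~is_plus]
        return plus, minus

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class Read:
    read_id: str
    chrom: str
    start: int
    strand: str
    length: int
    seq: str
    truncated: bool = False


@dataclass
class ReadSet:
    reads: list[Read]
    conversion_rate: float
    seed: int | None = None

    def to_sam(self, path, genome: SyntheticGenome) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": genome.name, "LN": len(genome)}],
            "CO": [f"noncpg simulator seed={self.seed} conversion_rate={self.conversion_rate}"],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.read_id
                a.query_sequence = r.seq
                a.flag = 0 if r.strand == "+" else 16
                a.reference_id = 0
                a.reference_start = r.start
                a.mapping_quality = 255
                a.cigarstring = f"{r.length}M"
                out.write(a)


def generate_genome(
    length: int,
    gc_background: float = 0.4,
    n_islands: int = 2,
    island_len: int = 500,
    msp1_spacing: float = 150,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate a genome with planted CCGG sites and CG-island-like regions.

    Background bases are i.i.d. with the requested GC fraction. Islands emit
    CG dinucleotides at an elevated rate so their observed CpG frequency is
    well above twice background. CCGG sites are planted at geometrically
    distributed spacings with the requested mean, giving an MspI fragment
    length distribution with substantial mass in the 40-260 bp window.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 bp")
    if not 0 < gc_background < 1:
        raise ValueError("gc_background must be in (0, 1)")
    if n_islands > 0 and n_islands * island_len >= length:
        raise ValueError("islands would cover the whole genome")
    rng = np.random.default_rng(seed)

    gc = gc_background
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(bases, size=length, p=probs)

    # islands: CG-rich stretches at evenly spread, jittered starts
    islands: list[tuple[int, int]] = []
    if n_islands > 0:
        slot = length // n_islands
        for i in range(n_islands):
            lo = i * slot
            hi = min(lo + slot - island_len, length - island_len)
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            islands.append((start, start + island_len))
            j = start
            while j < start + island_len - 1:
                if rng.random() < 0.15:
                    seq[j], seq[j + 1] = "C", "G"
                    j += 2
                else:
                    seq[j] = rng.choice(bases, p=[0.2, 0.3, 0.3, 0.2])
                    j += 1

    # plant CCGG sites at geometric spacings (mean = msp1_spacing)
    if msp1_spacing < length:
        p = min(1.0, 1.0 / msp1_spacing)
        pos = int(rng.geometric(p))
        while pos + 4 <= length:
            seq[pos : pos + 4] = list("CCGG")
            pos += max(4, int(rng.geometric(p)))

    features = [("CGI", s, e) for s, e in islands]
    return SyntheticGenome(
        name="chrS", sequence="".join(seq), features=features, islands=islands, seed=seed
    )


def assign_methylation(
    genome: SyntheticGenome,
    cpg_low_frac: float = 0.3,
    cpg_high_mean: float = 0.92,
    cpa_rate: float = CPA_MEAN_PRESETS["pluripotent"],
    noise_level: float = 0.0,
    seed: int = 0,
    cpg_low_mean: float = 0.03,
    island_low_frac: float = 0.9,
) -> MethylationTruth:
    """Draw per-site true methylation levels for every cytosine on both strands.

    CpG levels come from a two-component mixture: a low component (mean
    ``cpg_low_mean`` < 0.10) and a high component (mean ``cpg_high_mean`` >
    0.85), with island CpGs preferentially low (prob ``island_low_frac``) and
    non-island CpGs low with prob ``cpg_low_frac``. CpA levels are i.i.d.
    Exponential(mean=``cpa_rate``) truncated to [0, 1]. CpT/CpC are set to
    the constant ``noise_level``. Plus- and minus-strand cytosines are drawn
    independently (non-CpG methylation is asymmetric).
    """
    for name, v in [
        ("cpg_low_frac", cpg_low_frac),
        ("cpg_high_mean", cpg_high_mean),
        ("noise_level", noise_level),
        ("cpg_low_mean", cpg_low_mean),
        ("island_low_frac", island_low_frac),
    ]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    sites = cytosine_table(genome.sequence, genome.name)
    n = len(sites)
    level = np.zeros(n)
    ctx = sites["context"].to_numpy()
    pos = sites["pos0"].to_numpy()

    in_island = np.zeros(n, dtype=bool)
    for s, e in genome.islands:
        in_island |= (pos >= s) & (pos < e)

    is_cpg = ctx == "CpG"
    p_low = np.where(in_island, island_low_frac, cpg_low_frac)
    low = rng.random(n) < p_low
    # low component: supported strictly below 0.10 with the requested mean;
    # high component: beta concentrated at the requested mean (> 0.85)
    scale = 0.10
    mfrac, k_low = cpg_low_mean / scale, 10.0
    low_draw = scale * rng.beta(mfrac * k_low, (1 - mfrac) * k_low, size=n)
    k_high = 50.0
    high_draw = rng.beta(cpg_high_mean * k_high, (1 - cpg_high_mean) * k_high, size=n)
    level[is_cpg] = np.where(low, low_draw, high_draw)[is_cpg]

    is_cpa = ctx == "CpA"
    level[is_cpa] = np.minimum(rng.exponential(cpa_rate, size=int(is_cpa.sum())), 1.0)

    level[(ctx == "CpT") | (ctx == "CpC")] = noise_level

    table = sites.assign(true_level=level)
    return MethylationTruth(table=table, seed=seed)


def simulate_reads(
    genome: SyntheticGenome,
    truth: MethylationTruth,
    fragments,
    mean_coverage: float = 30,
    read_len: int = DEFAULT_READ_LEN,
    conversion_rate: float = DEFAULT_CONVERSION_RATE,
    seed: int = 0,
) -> ReadSet:
    """Simulate directional bisulfite reads over the size-selected fragments.

    For each cytosine covered by a read, the read shows the unconverted base
    with probability ``true_level + (1 - true_level) * (1 - conversion_rate)``
    and the converted base otherwise. Reads are emitted in plus-strand
    orientation: a plus-strand read reports plus-strand C's as C (unconverted)
    or T; a minus-strand read reports minus-strand C's (reference G positions)
    as G or A. Non-cytosine bases are copied from the reference. Reads longer
    than their fragment are truncated and flagged.
    """
    if not 0 <= conversion_rate <= 1:
        raise ValueError("conversion_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arr = seq_array(genome.sequence).copy()
    plus_lvl, minus_lvl = truth.level_arrays(len(genome))
    fail = 1.0 - conversion_rate

    reads: list[Read] = []
    rid = 0
    for fs, fe in fragments.selected_intervals():
        flen = fe - fs
        n_reads = rng.poisson(mean_coverage * flen / read_len)
        for _ in range(n_reads):
            truncated = flen < read_len
            rl = min(read_len, flen)
            start = fs if truncated else int(rng.integers(fs, fe - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ref = arr[start : start + rl]
            out = ref.copy()
            if strand == "+":
                cs = np.flatnonzero(ref == C)
                lv = plus_lvl[start + cs]
                lv = np.where(np.isnan(lv), 0.0, lv)
                p = lv + (1.0 - lv) * fail
                meth = rng.random(len(cs)) < p
                out[cs] = np.where(meth, ord("C"), ord("T"))
            else:
                gs = np.flatnonzero(ref == G)
                lv = minus_lvl[start + gs]
                lv = np.where(np.isnan(lv), 0.0, lv)
                p = lv + (1.0 - lv) * fail
                meth = rng.random(len(gs)) < p
                out[gs] = np.where(meth, ord("G"), ord("A"))
            reads.append(
                Read(
                    read_id=f"r{rid}",
                    chrom=genome.name,
                    start=start,
                    strand=strand,
                    length=rl,
                    seq=out.tobytes().decode("ascii"),
                    truncated=truncated,
                )
            )
            rid += 1
    return ReadSet(reads=reads, conversion_rate=conversion_rate, seed=seed)


def write_config(path, **params) -> None:
    """Record simulation parameters as a YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def simulate_expression_cohort(
    n_samples: int = 42,
    effect_dnmt3a: float = 0.5,
    effect_dnmt3b: float = 0.3,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample expression table with a planted DNMT3A/DNMT3B effect.

    Emulates a cohort in which mean CpA methylation is driven by de novo
    methyltransferase expression while pluripotency markers (OCT4, SOX2,
    NANOG) are uninformative. Log2 expression values are normalised to the
    ES-cell mean (mean ~ 0). The response column ``mean_cpa`` is on an
    arbitrary standardised scale.
    """
    rng = np.random.default_rng(seed)
    genes = ["DNMT3A", "DNMT3B", "DNMT1", "OCT4", "SOX2", "NANOG"]
    X = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_samples, len(genes))),
        columns=genes,
        index=[f"s{i}" for i in range(n_samples)],
    )
    y = (
        effect_dnmt3a * X["DNMT3A"]
        + effect_dnmt3b * X["DNMT3B"]
        + rng.normal(0.0, noise_sd, size=n_samples)
    )
    out = X.copy()
    out.insert(0, "mean_cpa", y)
    out.index.name = "sample_id"
    return out
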