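"""Shared sequence primitives: strand-specific cytosine enumeration and contexts.

A "site" throughout the package is a strand-specific cytosine identified by
(chrom, pos0, strand), with pos0 the 0-based position of the C on the plus
strand of the reference (for minus-strand cytosines this is the position of
the paired G). The context (CpG/CpA/CpT/CpC) is defined by the base
immediately 3' of the C on its own strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CpA", "CpT", "CpC")
NONCPG_CONTEXTS = ("CpA", "CpT", "CpC")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte codes used for vectorised scans
A, C, G, T = (np.uint8(ord(b)) for b in "ACGT")

# context of a plus-strand C given its 3' neighbour byte
_CTX_BY_NEIGHBOR = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("GATC"):  # index into CONTEXTS
    _CTX_BY_NEIGHBOR[ord(_b)] = _i


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 byte array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def cytosine_table(seq: str, chrom: str = "chr1") -> pd.DataFrame:
    """Enumerate every strand-specific cytosine that has a 3' neighbour.

    Returns a DataFrame with columns (chrom, pos0, strand, context) in genome
    order, plus strand before minus at the same position. Plus-strand
    cytosines are C's of the reference (context from the base at pos0+1);
    minus-strand cytosines sit at reference G's (their 3' neighbour on the
    minus strand is the complement of the base at pos0-1).
    """
    arr = seq_array(seq)
    pos_plus = np.flatnonzero(arr[:-1] == C)
    ctx_plus = _CTX_BY_NEIGHBOR[arr[pos_plus + 1]]
    keep = ctx_plus >= 0
    pos_plus, ctx_plus = pos_plus[keep], ctx_plus[keep]

    pos_minus = np.flatnonzero(arr[1:] == G) + 1
    # neighbour on the minus strand = complement of plus base at pos-1;
    # complement maps C->G, T->A, A->T, G->C, so look up via the pairing.
    comp_codes = np.full(256, 0, dtype=np.uint8)
    for b, cb in zip("ACGT", "TGCA"):
        comp_codes[ord(b)] = ord(cb)
    ctx_minus = _CTX_BY_NEIGHBOR[comp_codes[arr[pos_minus - 1]]]
    keep = ctx_minus >= 0
    pos_minus, ctx_minus = pos_minus[keep], ctx_minus[keep]

    ctx_labels = np.asarray(CONTEXTS, dtype=object)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": np.concatenate([pos_plus, pos_minus]),
            "strand": np.repeat(["+", "-"], [len(pos_plus), len(pos_minus)]),
            "context": np.concatenate(
                [ctx_labels[ctx_plus], ctx_labels[ctx_minus]]
            ),
        }
    )
    df = df.sort_values(["pos0", "strand"], ascending=[True, True], kind="stable")
    return df.reset_index(drop=True)


def site_context(seq: str, pos0: int, strand: str) -> str | None:
    """Context of a single strand-specific cytosine, or None if undefined."""
    if strand == "+":
        if seq[pos0] != "C" or pos0 + 1 >= len(seq):
            return None
        nb = seq[pos0 + 1]
    else:
        if seq[pos0] != "G" or pos0 == 0:
            return None
        nb = complement(seq[pos0 - 1])
    return {"G": "CpG", "A": "CpA", "T": "CpT", "C": "CpC"}.get(nb)
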