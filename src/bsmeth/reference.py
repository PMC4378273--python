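"""Reference-genome utilities: strand-specific cytosine enumeration and context.

Coordinates are 0-based, half-open throughout. A cytosine site is
strand-specific: a reference ``C`` is a site on the ``+`` strand, a reference
``G`` is a site on the ``-`` strand (its base on that strand is a C). A CpG
dinucleotide therefore contributes two sites, one per strand, never merged.

Sequence context (CpG / CHG / CHH, H = A, T or C) is read from the two bases
3' of the cytosine on its own strand. Sites too close to a contig edge to have
two downstream bases fall back to context ``CHH`` and are flagged
``context_complete = False`` so they can be excluded downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")


def seq_array(seq: str) -> np.ndarray:
    """Return the sequence as a 1-byte character array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1")


def context_of(arr: np.ndarray, pos: np.ndarray, strand: str) -> tuple[np.ndarray, np.ndarray]:
    """Context labels and completeness flags for cytosine positions on one strand.

    Parameters
    ----------
    arr : byte array of the reference sequence.
    pos : positions of cytosines on `strand` (reference C for ``+``, G for ``-``).
    strand : ``"+"`` or ``"-"``.
    """
    pos = np.asarray(pos, dtype=np.int64)
    n = len(arr)
    if strand == "+":
        has1 = pos + 1 < n
        has2 = pos + 2 < n
        b1 = np.where(has1, arr[np.minimum(pos + 1, n - 1)], b"N")
        b2 = np.where(has2, arr[np.minimum(pos + 2, n - 1)], b"N")
        is_g1 = b1 == b"G"
        is_g2 = b2 == b"G"
    elif strand == "-":
        # downstream on the minus strand runs leftward; complement of C is G,
        # so "next base is G (on the read strand)" means reference base is C
        has1 = pos - 1 >= 0
        has2 = pos - 2 >= 0
        b1 = np.where(has1, arr[np.maximum(pos - 1, 0)], b"N")
        b2 = np.where(has2, arr[np.maximum(pos - 2, 0)], b"N")
        is_g1 = b1 == b"C"
        is_g2 = b2 == b"C"
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    complete = has1 & has2
    context = np.where(
        has1 & is_g1, "CpG", np.where(complete & is_g2, "CHG", "CHH")
    )
    return context.astype(object), complete


def enumerate_cytosines(sequences: dict[str, str]) -> pd.DataFrame:
    """All strand-specific cytosine sites of a genome.

    Returns a frame with columns ``chrom, pos, strand, context,
    context_complete``, sorted by (chrom, pos, strand). The number of rows
    equals the count of C plus G bases in the sequences.
    """
    parts = []
    for chrom in sequences:
        arr = seq_array(sequences[chrom])
        for strand, base in (("+", b"C"), ("-", b"G")):
            pos = np.flatnonzero(arr == base).astype(np.int64)
            ctx, complete = context_of(arr, pos, strand)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": ctx,
                        "context_complete": complete,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "context_complete"]
        )
    out = pd.concat(parts, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )
    return out


def is_reference_cytosine(
    arr: np.ndarray, pos: np.ndarray, strand: np.ndarray
) -> np.ndarray:
    """True where `pos` holds a cytosine on the given strand of this sequence."""
    pos = np.asarray(pos, dtype=np.int64)
    ok = (pos >= 0) & (pos < len(arr))
    base = np.where(ok, arr[np.clip(pos, 0, len(arr) - 1)], b"N")
    want = np.where(np.asarray(strand) == "+", b"C", b"G")
    return ok & (base == want)
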