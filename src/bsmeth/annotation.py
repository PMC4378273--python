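"""Gene-model decomposition shared by the simulator, the IO layer and the
element summary.

A gene is an interval [start, end) with strand and exon sub-intervals; the
5' UTR occupies the first ``utr5_len`` transcript bases, the 3' UTR the last
``utr3_len``, exonic sequence between them is CDS, and inter-exon gaps are
introns. "Gene body" always means the full TSS-to-TTS span including introns
and UTRs.
"""

from __future__ import annotations

import pandas as pd


def gene_subfeatures(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Decompose genes into CDS / UTR5 / UTR3 / intron genomic intervals.

    `genes` needs gene_id/chrom/start/end/strand/utr5_len/utr3_len; `exons`
    needs gene_id/start/end. Returns ``gene_id, kind, chrom, start, end``.
    """
    rows = []
    exons_by_gene = dict(tuple(exons.groupby("gene_id", sort=False)))
    for g in genes.itertuples(index=False):
        ex = exons_by_gene[g.gene_id].sort_values("start")
        ivals = list(zip(ex["start"], ex["end"]))
        ivals_tx = ivals[::-1] if g.strand == "-" else ivals
        tx_len = sum(e - s for s, e in ivals)
        u5, u3 = min(g.utr5_len, tx_len), min(g.utr3_len, tx_len)
        offset = 0
        for s, e in ivals_tx:
            length = e - s
            for t0, t1, kind in (
                (0, u5, "UTR5"),
                (u5, tx_len - u3, "CDS"),
                (tx_len - u3, tx_len, "UTR3"),
            ):
                lo = max(t0, offset)
                hi = min(t1, offset + length)
                if hi > lo:
                    if g.strand == "+":
                        gs, ge = s + (lo - offset), s + (hi - offset)
                    else:
                        gs, ge = e - (hi - offset), e - (lo - offset)
                    rows.append((g.gene_id, kind, g.chrom, gs, ge))
            offset += length
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 > e1:
                rows.append((g.gene_id, "intron", g.chrom, e1, s2))
    return pd.DataFrame(rows, columns=["gene_id", "kind", "chrom", "start", "end"])
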