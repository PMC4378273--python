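"""Metagene methylation profiles by expression rank, and association tests.

Genes are ranked by expression: rank 0 collects silent genes (RPKM = 0) and
expressed genes are split by RPKM order into K equal-as-possible bins, 1
(least expressed) to K (most expressed). Profiles align genes at the TSS or
TTS, flip minus-strand genes so bins run 5'->3', and pool all eligible CpG
site levels from all genes of a rank into fixed 100-bp bins spanning a 2-kb
flank and 2 kb of gene body at each anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_rpkm(
    counts,
    lengths,
    library_size: float,
    scale_factors=None,
) -> np.ndarray:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = count * 1e9 / (length * library_size). When `scale_factors` is
    supplied each gene's RPKM is divided by its factor (a factor of 2 halves
    the value); the round trip ``compute_rpkm(...) * factors`` restores the
    unscaled values.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpkm = counts * 1e9 / (lengths * library_size)
    if scale_factors is not None:
        rpkm = rpkm / np.asarray(scale_factors, dtype=float)
    return rpkm


def rank_genes(rpkm_table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Expression ranks: 0 for silent genes, 1..k deciles for expressed ones.

    Expressed genes are sorted by (rpkm, gene_id) — the id breaks ties
    deterministically — and split into k contiguous groups whose sizes differ
    by at most one. Returns columns ``gene_id, rpkm, rank``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = rpkm_table[["gene_id", "rpkm"]].copy()
    out["rank"] = 0
    expressed = out[out["rpkm"] > 0].sort_values(
        ["rpkm", "gene_id"], kind="mergesort"
    )
    if len(expressed):
        chunks = np.array_split(expressed.index.to_numpy(), k)
        for i, idx in enumerate(chunks, start=1):
            out.loc[idx, "rank"] = i
    return out


@dataclass(frozen=True)
class ProfileWindows:
    flank: int = 2000
    body: int = 2000
    bin_width: int = 100


def metagene_profile(
    genes: pd.DataFrame,
    site_levels: pd.DataFrame,
    flank: int = 2000,
    body: int = 2000,
    bin_width: int = 100,
) -> pd.DataFrame:
    """Pooled per-bin mean methylation around TSS and TTS, per rank.

    `genes` needs chrom/start/end/strand and, optionally, a ``rank`` column
    (absent -> one pooled profile with rank -1). For each gene, eligible CpG
    site levels are placed at signed distances from the anchor in 5'->3'
    orientation: at the TSS, distance 0 is the first body base and negative
    distances are upstream flank; at the TTS, distance 0 is the first base
    past the gene and negative distances are body. Genes shorter than the
    body window contribute only the bins they cover. Bin index =
    floor(distance / bin_width). Empty bins are absent.
    """
    if bin_width < 1 or flank < 0 or body < 0:
        raise ValueError("invalid window parameters")
    elig = site_levels[(site_levels["context"] == "CpG") & site_levels["eligible"]]
    pos_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in elig.groupby("chrom", sort=False, observed=True):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        pos_by_chrom[str(chrom)] = (
            sub["pos"].to_numpy()[order],
            sub["level"].to_numpy(float)[order],
        )

    has_rank = "rank" in genes.columns
    acc_sum: dict[tuple[int, str, int], float] = {}
    acc_n: dict[tuple[int, str, int], int] = {}
    for g in genes.itertuples(index=False):
        chrom_data = pos_by_chrom.get(g.chrom)
        if chrom_data is None:
            continue
        pos, lvl = chrom_data
        rank = int(g.rank) if has_rank else -1
        glen = g.end - g.start
        lo, hi = np.searchsorted(pos, [g.start - flank, g.end + flank])
        p = pos[lo:hi]
        v = lvl[lo:hi]
        if g.strand == "+":
            d_tss = p - g.start
            d_tts = p - g.end
        else:
            d_tss = (g.end - 1) - p
            d_tts = (g.start - 1) - p
        for anchor, d in (("TSS", d_tss), ("TTS", d_tts)):
            if anchor == "TSS":
                keep = (d >= -flank) & (d < min(body, glen))
            else:
                keep = (d >= -min(body, glen)) & (d < flank)
            if not keep.any():
                continue
            bins = np.floor_divide(d[keep], bin_width)
            for b, val in zip(bins, v[keep]):
                key = (rank, anchor, int(b))
                acc_sum[key] = acc_sum.get(key, 0.0) + float(val)
                acc_n[key] = acc_n.get(key, 0) + 1

    rows = [
        (
            rank,
            anchor,
            b,
            b * bin_width,
            acc_sum[(rank, anchor, b)] / acc_n[(rank, anchor, b)],
            acc_n[(rank, anchor, b)],
        )
        for (rank, anchor, b) in sorted(acc_n)
    ]
    return pd.DataFrame(
        rows,
        columns=["rank", "anchor", "bin", "rel_start", "mean_level", "n_sites"],
    )


@dataclass(frozen=True)
class AssociationResult:
    spearman_r: float
    spearman_p: float
    n: int
    wilcoxon_p: float  # one-sided: methylated genes are longer
    n_methylated: int
    n_unmethylated: int


def length_association(genes: pd.DataFrame) -> AssociationResult:
    """Spearman of body level vs gene length, plus a one-sided rank-sum test
    that methylated genes are longer than unmethylated ones."""
    df = genes.dropna(subset=["level"])
    if len(df) < 3:
        raise ValueError("need >= 3 genes with a defined body methylation level")
    length = df["length"] if "length" in df.columns else df["end"] - df["start"]
    if df["level"].nunique() < 2 or pd.Series(length).nunique() < 2:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.spearmanr(df["level"], length)
    meth = np.asarray(length)[df["status"] == "methylated"]
    unmeth = np.asarray(length)[df["status"] == "unmethylated"]
    if len(meth) and len(unmeth):
        w = stats.mannwhitneyu(meth, unmeth, alternative="greater").pvalue
    else:
        w = float("nan")
    return AssociationResult(
        spearman_r=float(r),
        spearman_p=float(p),
        n=len(df),
        wilcoxon_p=float(w),
        n_methylated=int(len(meth)),
        n_unmethylated=int(len(unmeth)),
    )


@dataclass(frozen=True)
class ExpressionAssociation:
    spearman_r_all: float
    spearman_p_all: float
    n_all: int
    spearman_r_excluded: float  # after dropping the top expressed fraction
    spearman_p_excluded: float
    n_excluded: int


def expression_association(
    genes: pd.DataFrame, exclude_top_fraction: float = 0.2
) -> ExpressionAssociation:
    """Spearman of body level vs RPKM, with and without the most highly
    expressed genes (top `exclude_top_fraction` by RPKM dropped before the
    second correlation)."""
    if not 0.0 <= exclude_top_fraction < 1.0:
        raise ValueError("exclude_top_fraction must lie in [0, 1)")
    df = genes.dropna(subset=["level"])
    if len(df) < 3:
        raise ValueError("need >= 3 genes with a defined body methylation level")

    def _spear(sub: pd.DataFrame) -> tuple[float, float]:
        if len(sub) < 3 or sub["level"].nunique() < 2 or sub["rpkm"].nunique() < 2:
            return float("nan"), float("nan")
        r, p = stats.spearmanr(sub["level"], sub["rpkm"])
        return float(r), float(p)

    r_all, p_all = _spear(df)
    n_drop = int(len(df) * exclude_top_fraction)
    kept = df.sort_values(["rpkm", "gene_id"], kind="mergesort")
    kept = kept.iloc[: len(df) - n_drop] if n_drop else kept
    r_ex, p_ex = _spear(kept)
    return ExpressionAssociation(
        spearman_r_all=r_all,
        spearman_p_all=p_all,
        n_all=len(df),
        spearman_r_excluded=r_ex,
        spearman_p_excluded=p_ex,
        n_excluded=len(kept),
    )
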