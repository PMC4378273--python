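"""Site and region methylation levels, element summaries, mCG density.

A site's methylation level is its C-read count over its depth; only sites
covered by at least 5 reads are *eligible* for level analyses. A region's
level is the unweighted mean of the levels of the eligible CpG sites it
contains (strand-agnostic interval overlap), never a read-count-weighted
average. A region holding at least 2 called mCGs — regardless of the 5X
eligibility of those sites — is classified methylated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ELEMENT_KINDS = (
    "CDS",
    "UTR5",
    "UTR3",
    "intron",
    "tRNA",
    "snRNA",
    "rRNA",
    "upstream2k",
    "downstream2k",
    "other",
)


def site_level(c_count: int, depth: int, min_depth: int = 5) -> tuple[float, bool]:
    """Level (c/depth) and 5X eligibility for one site."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return c_count / depth, depth >= min_depth


def add_site_levels(sites: pd.DataFrame, min_depth: int = 5) -> pd.DataFrame:
    """Attach ``level`` and ``eligible`` columns to a site/call table."""
    out = sites.copy()
    out["level"] = out["c_count"] / out["depth"]
    out["eligible"] = out["depth"] >= min_depth
    return out


class _PosIndex:
    """Sorted per-chromosome position index for count/sum queries over
    half-open intervals. Sums are taken directly over the selected slice so
    a region's mean is bit-identical to the plain mean of its member sites."""

    def __init__(self, df: pd.DataFrame, value_col: str | None = None):
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False, observed=True):
            order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
            self._pos[str(chrom)] = sub["pos"].to_numpy()[order]
            if value_col is not None:
                self._val[str(chrom)] = sub[value_col].to_numpy(float)[order]

    def count(self, chrom: str, start: int, end: int) -> int:
        p = self._pos.get(chrom)
        if p is None:
            return 0
        lo, hi = np.searchsorted(p, [start, end])
        return int(hi - lo)

    def sum(self, chrom: str, start: int, end: int) -> float:
        p = self._pos.get(chrom)
        if p is None:
            return 0.0
        lo, hi = np.searchsorted(p, [start, end])
        # exactly-rounded summation: the region mean is then independent of
        # site ordering and bit-identical to a brute-force mean
        return math.fsum(self._val[chrom][lo:hi])


@dataclass(frozen=True)
class RegionLevel:
    """Methylation summary of one genomic interval."""

    level: float  # NaN when no eligible CpG falls in the region
    n_covered_cpgs: int
    n_mcgs: int
    status: str  # "methylated" iff n_mcgs >= min_mcgs


def _indices(site_levels: pd.DataFrame, calls: pd.DataFrame | None):
    elig = site_levels[
        (site_levels["context"] == "CpG") & site_levels["eligible"]
    ]
    elig_idx = _PosIndex(elig, value_col="level")
    if calls is not None:
        mcg = calls[(calls["context"] == "CpG") & calls["is_methylated"]]
        mcg_idx = _PosIndex(mcg)
    else:
        mcg_idx = _PosIndex(pd.DataFrame(columns=["chrom", "pos"]))
    return elig_idx, mcg_idx


def region_level(
    chrom: str,
    start: int,
    end: int,
    site_levels: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    min_mcgs: int = 2,
) -> RegionLevel:
    """Unweighted mean level of eligible CpGs in [start, end), plus status."""
    if start >= end:
        raise ValueError("region must satisfy start < end")
    elig_idx, mcg_idx = _indices(site_levels, calls)
    n = elig_idx.count(chrom, start, end)
    lvl = elig_idx.sum(chrom, start, end) / n if n else float("nan")
    n_mcgs = mcg_idx.count(chrom, start, end)
    status = "methylated" if n_mcgs >= min_mcgs else "unmethylated"
    return RegionLevel(level=lvl, n_covered_cpgs=n, n_mcgs=n_mcgs, status=status)


def feature_methylation(
    features: pd.DataFrame,
    site_levels: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    ref_cpgs: pd.DataFrame | None = None,
    min_mcgs: int = 2,
    coverage_min_depth: int = 2,
) -> pd.DataFrame:
    """Per-feature region levels for a table of intervals.

    Adds ``level, n_covered_cpgs, n_mcgs, status`` to `features` (which must
    carry chrom/start/end). When `ref_cpgs` (all reference CpG sites) is
    given, also adds ``cpg_coverage_fraction``: the fraction of the feature's
    reference CpGs covered by at least `coverage_min_depth` reads.
    """
    elig_idx, mcg_idx = _indices(site_levels, calls)
    if ref_cpgs is not None:
        ref_idx = _PosIndex(ref_cpgs[ref_cpgs["context"] == "CpG"])
        cov = site_levels[
            (site_levels["context"] == "CpG")
            & (site_levels["depth"] >= coverage_min_depth)
        ]
        cov_idx = _PosIndex(cov)
    out = features.copy()
    levels, ns, mcgs, fracs = [], [], [], []
    for f in features.itertuples(index=False):
        n = elig_idx.count(f.chrom, f.start, f.end)
        levels.append(elig_idx.sum(f.chrom, f.start, f.end) / n if n else np.nan)
        ns.append(n)
        mcgs.append(mcg_idx.count(f.chrom, f.start, f.end))
        if ref_cpgs is not None:
            n_ref = ref_idx.count(f.chrom, f.start, f.end)
            n_cov = cov_idx.count(f.chrom, f.start, f.end)
            fracs.append(n_cov / n_ref if n_ref else np.nan)
    out["level"] = levels
    out["n_covered_cpgs"] = ns
    out["n_mcgs"] = mcgs
    out["status"] = np.where(
        np.asarray(mcgs) >= min_mcgs, "methylated", "unmethylated"
    )
    if ref_cpgs is not None:
        out["cpg_coverage_fraction"] = fracs
    return out


_PRIORITY = {
    "CDS": 0,
    "UTR5": 1,
    "UTR3": 1,
    "intron": 2,
    "tRNA": 3,
    "snRNA": 3,
    "rRNA": 3,
    # repeat classes get priority 4 (added dynamically)
    "upstream2k": 5,
    "downstream2k": 5,
    "other": 9,
}


def element_summary(
    site_levels: pd.DataFrame,
    gene_features: pd.DataFrame,  # gene_id kind chrom start end (CDS/UTR5/UTR3/intron)
    genes: pd.DataFrame,  # gene_id chrom start end strand (for 2-kb flanks)
    repeats: pd.DataFrame,  # chrom start end rclass
    ncrnas: pd.DataFrame,  # chrom start end kind
    chrom_lengths: dict[str, int],
    flank: int = 2000,
    exclude_chroms: tuple[str, ...] = ("spike",),
) -> pd.DataFrame:
    """Mean methylation level per genomic element kind.

    Each eligible CpG is assigned to exactly one kind by precedence: gene
    sub-features (CDS > UTR > intron) > ncRNA > repeat > 2-kb flank > other,
    where "other" is everything not claimed by a named element or flank.
    Kinds with no assigned site are absent from the output (an empty "other"
    is logged). Returns columns ``kind, level, n_sites``.
    """
    elig = site_levels[
        (site_levels["context"] == "CpG")
        & site_levels["eligible"]
        & ~site_levels["chrom"].isin(exclude_chroms)
    ]
    labels: list[str] = []
    label_code: dict[str, int] = {}

    def code(label: str) -> int:
        if label not in label_code:
            label_code[label] = len(labels)
            labels.append(label)
        return label_code[label]

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom, sub in elig.groupby("chrom", sort=False, observed=True):
        chrom = str(chrom)
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        pos = sub["pos"].to_numpy()[order]
        lvl = sub["level"].to_numpy(float)[order]
        prio = np.full(len(pos), 99, dtype=np.int8)
        kind = np.full(len(pos), -1, dtype=np.int32)

        def stamp(start, end, label, p):
            lo, hi = np.searchsorted(pos, [max(0, start), min(chrom_lengths[chrom], end)])
            sel = slice(lo, hi)
            better = prio[sel] > p
            kind[sel] = np.where(better, code(label), kind[sel])
            prio[sel] = np.where(better, p, prio[sel])

        for f in gene_features[gene_features["chrom"] == chrom].itertuples(index=False):
            stamp(f.start, f.end, f.kind, _PRIORITY[f.kind])
        for f in ncrnas[ncrnas["chrom"] == chrom].itertuples(index=False):
            stamp(f.start, f.end, f.kind, _PRIORITY[f.kind])
        for f in repeats[repeats["chrom"] == chrom].itertuples(index=False):
            stamp(f.start, f.end, f"repeat:{f.rclass}", 4)
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            up = (g.start - flank, g.start) if g.strand == "+" else (g.end, g.end + flank)
            dn = (g.end, g.end + flank) if g.strand == "+" else (g.start - flank, g.start)
            stamp(up[0], up[1], "upstream2k", _PRIORITY["upstream2k"])
            stamp(dn[0], dn[1], "downstream2k", _PRIORITY["downstream2k"])
        kind[kind < 0] = code("other")

        for k in np.unique(kind):
            sel = kind == k
            sums[int(k)] = sums.get(int(k), 0.0) + float(lvl[sel].sum())
            counts[int(k)] = counts.get(int(k), 0) + int(sel.sum())

    rows = [
        (labels[k], sums[k] / counts[k], counts[k])
        for k in sorted(counts, key=lambda k: labels[k])
    ]
    out = pd.DataFrame(rows, columns=["kind", "level", "n_sites"])
    if "other" not in set(out["kind"]):
        logger.warning(
            "element_summary: no eligible CpG left in the 'other' category "
            "(genome fully covered by named elements and flanks)"
        )
    return out.sort_values("kind").reset_index(drop=True)


def mcg_density_track(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 1000,
    exclude_chroms: tuple[str, ...] = ("spike",),
) -> pd.DataFrame:
    """mCG count per non-overlapping window divided by the window length.

    Windows tile each chromosome from position 0; the last, possibly partial,
    window is divided by its actual length. Both strands' mCGs count.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mcg = calls[(calls["context"] == "CpG") & calls["is_methylated"]]
    rows = []
    for chrom, length in chrom_lengths.items():
        if chrom in exclude_chroms:
            continue
        p = np.sort(mcg.loc[mcg["chrom"] == chrom, "pos"].to_numpy())
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        counts = np.searchsorted(p, ends) - np.searchsorted(p, starts)
        for s, e, n in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), int(n), n / (e - s)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_mcgs", "density"]
    )


@dataclass(frozen=True)
class RepeatDivergenceResult:
    """Level-divergence correlation and methylated-vs-unmethylated ages."""

    spearman_r: float
    spearman_p: float
    n: int
    wilcoxon_p: float  # one-sided: methylated repeats diverge less
    n_methylated: int
    n_unmethylated: int


def repeat_divergence_analysis(repeats: pd.DataFrame) -> RepeatDivergenceResult:
    """Spearman correlation of repeat level vs divergence, and a one-sided
    Wilcoxon rank-sum test that methylated repeats have lower divergence."""
    df = repeats.dropna(subset=["level"])
    if len(df) < 3:
        raise ValueError("need >= 3 repeats with a defined methylation level")
    if df["level"].nunique() < 2 or df["divergence"].nunique() < 2:
        r, p = float("nan"), float("nan")  # correlation undefined
    else:
        r, p = stats.spearmanr(df["level"], df["divergence"])
    meth = df.loc[df["status"] == "methylated", "divergence"]
    unmeth = df.loc[df["status"] == "unmethylated", "divergence"]
    if len(meth) and len(unmeth):
        w = stats.mannwhitneyu(meth, unmeth, alternative="less").pvalue
    else:
        w = float("nan")
    return RepeatDivergenceResult(
        spearman_r=float(r),
        spearman_p=float(p),
        n=len(df),
        wilcoxon_p=float(w),
        n_methylated=len(meth),
        n_unmethylated=len(unmeth),
    )
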