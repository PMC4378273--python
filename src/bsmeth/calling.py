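"""Binomial methylcytosine calling with Benjamini-Hochberg FDR control.

At an unmethylated cytosine every observed C read is error (bisulfite
non-conversion or a T-to-C sequencing error), so under the null the C count
at a site of depth *n* is Binomial(*n*, *e*) with *e* the spike-in-estimated
error rate. A site's p-value is the upper tail P(X >= c); p-values for all
covered cytosines of a library (all contexts jointly) are BH-adjusted and a
site is called methylated when its adjusted value falls below ``alpha``
(default 0.01, i.e. FDR under 1%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def binomial_pvalue(c_count: int, depth: int, error_rate: float) -> float:
    """Upper-tail P(X >= c_count) for X ~ Binomial(depth, error_rate)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= c_count <= depth:
        raise ValueError("c_count must lie in [0, depth]")
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie in (0, 1)")
    return float(stats.binom.sf(c_count - 1, depth, error_rate))


def call_methylation(
    sites: pd.DataFrame, error_rate: float, alpha: float = 0.01
) -> pd.DataFrame:
    """Test every covered site and flag methylated cytosines at FDR < alpha.

    Any site with at least one read is tested; coverage-based denominators
    (the >=2X rule) apply only to summary percentages, not to calling.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if sites.empty:
        raise ValueError("no sites to test")
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must lie in (0, 1), got {error_rate}")
    depth = sites["depth"].to_numpy(np.int64)
    if (depth <= 0).any():
        raise ValueError("all sites must have depth >= 1")
    c = sites["c_count"].to_numpy(np.int64)
    p = stats.binom.sf(c - 1, depth, error_rate)
    q = multipletests(p, method="fdr_bh")[1]
    out = sites.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["is_methylated"] = q < alpha
    return out


@dataclass(frozen=True)
class GenomeSummary:
    """Genome-wide methylation percentages (Table-1-style).

    Denominators use sites covered by at least ``min_depth`` (default 2)
    reads; the context breakdown is over all identified mCs.
    """

    pct_mc_of_covered_cs: float
    pct_mcg_of_covered_cpgs: float
    context_breakdown: dict[str, float]
    n_covered_cs: int
    n_covered_cpgs: int
    n_mcs: int


def summarize_genome(
    calls: pd.DataFrame, min_depth: int = 2, exclude_chroms: tuple[str, ...] = ()
) -> GenomeSummary:
    """Percent mC of covered Cs, percent mCG of covered CpGs, context split."""
    sub = calls[~calls["chrom"].isin(exclude_chroms)] if exclude_chroms else calls
    covered = sub[sub["depth"] >= min_depth]
    if covered.empty:
        raise ValueError(f"no sites with depth >= {min_depth}")
    is_cpg = covered["context"] == "CpG"
    n_cs = len(covered)
    n_cpgs = int(is_cpg.sum())
    mc_cov = covered["is_methylated"]
    pct_mc = 100.0 * mc_cov.sum() / n_cs
    pct_mcg = 100.0 * (mc_cov & is_cpg).sum() / n_cpgs if n_cpgs else float("nan")

    mcs = sub[sub["is_methylated"]]
    n_mcs = len(mcs)
    breakdown = {}
    for ctx, label in (("CpG", "CG"), ("CHG", "CHG"), ("CHH", "CHH")):
        breakdown[label] = (
            100.0 * (mcs["context"] == ctx).sum() / n_mcs if n_mcs else 0.0
        )
    return GenomeSummary(
        pct_mc_of_covered_cs=float(pct_mc),
        pct_mcg_of_covered_cpgs=float(pct_mcg),
        context_breakdown=breakdown,
        n_covered_cs=n_cs,
        n_covered_cpgs=n_cpgs,
        n_mcs=n_mcs,
    )
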