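"""Read-stack filtering, per-cytosine pileup and spike-in error-rate estimation.

The read stack is the post-alignment contract: one row per (read, cytosine)
with the observed base, its phred quality, and the read's start position.
Filtering removes sub-threshold bases and collapses PCR duplicates; the
pileup turns the surviving evidence into per-site C/T counts with sequence
context; the error rate (bisulfite non-conversion plus T-to-C sequencing
error) is the total C count over the total depth at cytosines of the
unmethylated spike-in contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import context_of, is_reference_cytosine, seq_array

logger = logging.getLogger(__name__)

STACK_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "observed_base",
    "base_quality",
    "read_start",
    "read_id",
]

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "c_count", "depth"]


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Library error rate from the unmethylated spike-in contig."""

    error_rate: float
    spike_c_total: int
    spike_depth_total: int


def filter_read_stack(stack: pd.DataFrame, min_quality: int = 30) -> pd.DataFrame:
    """Quality-filter and PCR-deduplicate a read stack.

    Bases with phred quality below ``min_quality`` are dropped. Reads sharing
    the same mapping position (chrom, read_start, strand) are PCR duplicates:
    a single read is retained per position — the one whose best base quality
    is highest, ties broken by smallest read_id — and all of its remaining
    bases are kept. Idempotent; an empty stack passes through unchanged.
    """
    if stack.empty:
        return stack.copy()
    kept = stack[stack["base_quality"] >= min_quality]
    if kept.empty:
        return kept.copy()
    reads = (
        kept.groupby("read_id", sort=False)
        .agg(
            chrom=("chrom", "first"),
            read_start=("read_start", "first"),
            strand=("strand", "first"),
            best_q=("base_quality", "max"),
        )
        .reset_index()
    )
    reads = reads.sort_values(
        ["chrom", "read_start", "strand", "best_q", "read_id"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    winners = reads.drop_duplicates(["chrom", "read_start", "strand"])["read_id"]
    out = kept[kept["read_id"].isin(winners.to_numpy())].copy()
    logger.info(
        "filter_read_stack: %d entries in, %d after quality, %d after dedup",
        len(stack),
        len(kept),
        len(out),
    )
    return out


def pile_counts(stack: pd.DataFrame, sequences: dict[str, str]) -> pd.DataFrame:
    """Collapse filtered stack entries into per-cytosine C/T counts.

    One output row per (chrom, pos, strand) holding C/T evidence; observed
    bases other than C/T are ignored and do not count toward depth. Entries
    whose position is not a reference cytosine on the claimed strand are
    rejected; the rejection count is logged and exposed as
    ``result.attrs["n_rejected"]``.
    """
    if stack.empty:
        out = pd.DataFrame(columns=SITE_COLUMNS)
        out.attrs["n_rejected"] = 0
        return out

    ct = stack[stack["observed_base"].isin(["C", "T"])]

    # validate against the reference, per chromosome
    keep_parts = []
    n_rejected = 0
    for chrom, sub in ct.groupby("chrom", sort=False):
        if chrom not in sequences:
            n_rejected += len(sub)
            continue
        arr = seq_array(sequences[chrom])
        ok = is_reference_cytosine(
            arr, sub["pos"].to_numpy(), sub["strand"].to_numpy()
        )
        n_rejected += int((~ok).sum())
        keep_parts.append(sub[ok])
    if n_rejected:
        logger.warning(
            "pile_counts: rejected %d entries not at a reference cytosine",
            n_rejected,
        )
    if not keep_parts:
        out = pd.DataFrame(columns=SITE_COLUMNS)
        out.attrs["n_rejected"] = n_rejected
        return out
    ct = pd.concat(keep_parts, ignore_index=True)

    grouped = (
        ct.assign(is_c=(ct["observed_base"] == "C").astype(np.int64))
        .groupby(["chrom", "pos", "strand"], sort=True, observed=True)
        .agg(c_count=("is_c", "sum"), depth=("is_c", "size"))
        .reset_index()
    )

    ctx_parts = []
    for chrom, sub in grouped.groupby("chrom", sort=False):
        arr = seq_array(sequences[chrom])
        for strand in ("+", "-"):
            ss = sub[sub["strand"] == strand]
            if ss.empty:
                continue
            ctx, complete = context_of(arr, ss["pos"].to_numpy(), strand)
            ss = ss.copy()
            ss["context"] = ctx
            ss["context_complete"] = complete
            ctx_parts.append(ss)
    out = pd.concat(ctx_parts, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )
    out = out[SITE_COLUMNS + ["context_complete"]]
    out.attrs["n_rejected"] = n_rejected
    logger.info("pile_counts: %d sites from %d entries", len(out), len(stack))
    return out


def estimate_error_rate(
    sites: pd.DataFrame, spike_chrom: str = "spike"
) -> ErrorRateEstimate:
    """Error rate = total C count / total depth over spike-in cytosines."""
    spike = sites[sites["chrom"] == spike_chrom]
    c_total = int(spike["c_count"].sum())
    depth_total = int(spike["depth"].sum())
    if depth_total == 0:
        raise ValueError(
            f"no covered cytosines on spike-in contig {spike_chrom!r}; "
            "cannot estimate the error rate"
        )
    return ErrorRateEstimate(
        error_rate=c_total / depth_total,
        spike_c_total=c_total,
        spike_depth_total=depth_total,
    )
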