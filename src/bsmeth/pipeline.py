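"""End-to-end pipeline: extraction -> error rate -> calling -> levels ->
profiles/associations -> phylostratigraphy, with auditable stage logging.

Every output table is stamped with the configuration hash; a rerun with the
same inputs and configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as bio
from .annotation import gene_subfeatures
from .calling import GenomeSummary, call_methylation, summarize_genome
from .config import PipelineConfig
from .phylostrat import (
    PhylostratumMap,
    assign_phylostrata,
    go_enrichment,
    methylation_by_age,
)
from .profiles import (
    expression_association,
    length_association,
    metagene_profile,
    rank_genes,
)
from .reference import enumerate_cytosines
from .regions import (
    add_site_levels,
    element_summary,
    feature_methylation,
    mcg_density_track,
    repeat_divergence_analysis,
)
from .sites import estimate_error_rate, filter_read_stack, pile_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    error_rate: float
    calls: pd.DataFrame
    genome_summary: GenomeSummary
    genes: pd.DataFrame
    repeats: pd.DataFrame
    elements: pd.DataFrame
    density: pd.DataFrame
    profiles: pd.DataFrame
    repeat_divergence: object
    length_assoc: object
    expression_assoc: object
    age_table: pd.DataFrame
    enrichment: pd.DataFrame
    counts: dict = field(default_factory=dict)  # records in/out per stage


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage from files named in `config`; optionally write outputs."""
    config.validate()
    chash = config.config_hash()
    counts: dict[str, int] = {}

    sequences = bio.read_fasta(config.genome_fasta)
    genes, exons = bio.read_gff3(config.genes_gff3)
    repeats = bio.read_repeat_bed(config.repeats_bed)
    ncrnas = bio.read_ncrna_bed(config.ncrna_bed)
    stack = bio.read_stack_tsv(config.stack_tsv)
    counts["stack_entries_in"] = len(stack)

    # stage 1: extraction
    filtered = filter_read_stack(stack, min_quality=config.min_quality)
    counts["stack_entries_filtered"] = len(filtered)
    sites = pile_counts(filtered, sequences)
    counts["sites"] = len(sites)
    counts["pile_rejected"] = sites.attrs.get("n_rejected", 0)

    # stage 2: error rate
    if config.error_rate is not None:
        error_rate = config.error_rate
    else:
        if config.spike_chrom not in sequences:
            raise ValueError(
                f"spike-in contig {config.spike_chrom!r} absent from the genome "
                "and no explicit error_rate supplied; cannot calibrate the caller"
            )
        est = estimate_error_rate(sites, spike_chrom=config.spike_chrom)
        error_rate = est.error_rate
    counts["error_rate_ppm"] = int(round(error_rate * 1e6))

    # stage 3: calling
    calls = call_methylation(sites, error_rate, alpha=config.alpha)
    counts["mcs_called"] = int(calls["is_methylated"].sum())
    summary = summarize_genome(
        calls,
        min_depth=config.coverage_min_depth,
        exclude_chroms=(config.spike_chrom,),
    )

    # stage 4: levels
    site_levels = add_site_levels(calls, min_depth=config.level_min_depth)
    counts["eligible_sites"] = int(site_levels["eligible"].sum())
    ref_sites = enumerate_cytosines(sequences)
    genes = genes.assign(length=genes["end"] - genes["start"])
    gene_table = feature_methylation(
        genes,
        site_levels,
        calls,
        ref_cpgs=ref_sites,
        min_mcgs=config.methylated_min_mcgs,
        coverage_min_depth=config.coverage_min_depth,
    )
    repeat_table = feature_methylation(
        repeats,
        site_levels,
        calls,
        min_mcgs=config.methylated_min_mcgs,
    )
    chrom_lengths = {c: len(s) for c, s in sequences.items()}
    elements = element_summary(
        site_levels,
        gene_subfeatures(genes, exons),
        genes,
        repeats,
        ncrnas,
        chrom_lengths,
        flank=config.flank,
        exclude_chroms=(config.spike_chrom,),
    )
    density = mcg_density_track(
        calls, chrom_lengths, window=config.window,
        exclude_chroms=(config.spike_chrom,),
    )
    repeat_div = (
        repeat_divergence_analysis(repeat_table)
        if repeat_table["level"].notna().sum() >= 3
        else None
    )

    # stage 5: profiles and associations
    expr = bio.read_expression_tsv(config.expression_tsv)
    gene_table = gene_table.merge(expr, on="gene_id", how="left")
    gene_table["rpkm"] = gene_table["rpkm"].fillna(0.0)
    ranks = rank_genes(gene_table[["gene_id", "rpkm"]], k=config.rank_bins)
    gene_table = gene_table.merge(ranks[["gene_id", "rank"]], on="gene_id")
    passing = gene_table[
        gene_table["cpg_coverage_fraction"] >= config.gene_coverage_fraction
    ]
    counts["genes_passing_coverage"] = len(passing)
    profiles = metagene_profile(
        passing, site_levels, flank=config.flank, body=config.flank
    )
    length_assoc = length_association(passing) if len(passing) >= 3 else None
    expr_assoc = (
        expression_association(passing, config.exclude_top_fraction)
        if len(passing) >= 3
        else None
    )

    # stage 6: phylostratigraphy
    hits = bio.read_hits_tsv(config.hits_tsv)
    smap = bio.read_species_map_tsv(config.species_map_tsv)
    pmap = PhylostratumMap(
        species_to_node=dict(zip(smap["species"], smap["node"]))
    )
    strata = assign_phylostrata(
        hits, pmap, gene_table["gene_id"], focal_species=config.focal_species
    )
    gene_table = gene_table.merge(
        strata.reset_index(), on="gene_id", how="left"
    )
    age_table = methylation_by_age(
        gene_table, min_coverage_fraction=config.gene_coverage_fraction
    )
    go = bio.read_go_tsv(config.go_tsv)
    background = set(gene_table["gene_id"])
    enrich_parts = []
    for stratum, sub in gene_table.groupby("phylostratum"):
        if len(sub) < 3:
            continue
        res = go_enrichment(
            set(sub["gene_id"]), background, go, alpha=config.enrichment_alpha
        )
        res.insert(0, "phylostratum", int(stratum))
        enrich_parts.append(res)
    enrichment = (
        pd.concat(enrich_parts, ignore_index=True)
        if enrich_parts
        else pd.DataFrame()
    )

    result = PipelineResult(
        error_rate=error_rate,
        calls=calls,
        genome_summary=summary,
        genes=gene_table,
        repeats=repeat_table,
        elements=elements,
        density=density,
        profiles=profiles,
        repeat_divergence=repeat_div,
        length_assoc=length_assoc,
        expression_assoc=expr_assoc,
        age_table=age_table,
        enrichment=enrichment,
        counts=counts,
    )
    if write and config.outdir:
        write_results(result, config, chash)
    return result


def write_results(
    result: PipelineResult, config: PipelineConfig, chash: str
) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bio.write_output_table(result.calls, outdir / "calls.tsv", chash)
    bio.write_output_table(result.genes, outdir / "genes.tsv", chash)
    bio.write_output_table(result.repeats, outdir / "repeats.tsv", chash)
    bio.write_output_table(result.elements, outdir / "elements.tsv", chash)
    bio.write_output_table(result.density, outdir / "density.tsv", chash)
    bio.write_output_table(result.profiles, outdir / "profiles.tsv", chash)
    bio.write_output_table(result.age_table, outdir / "age_table.tsv", chash)
    bio.write_output_table(result.enrichment, outdir / "enrichment.tsv", chash)
    scalars = {
        "config": chash,
        "error_rate": result.error_rate,
        "pct_mc_of_covered_cs": result.genome_summary.pct_mc_of_covered_cs,
        "pct_mcg_of_covered_cpgs": result.genome_summary.pct_mcg_of_covered_cpgs,
        "context_breakdown": result.genome_summary.context_breakdown,
        "counts": result.counts,
    }
    for name, res in (
        ("repeat_divergence", result.repeat_divergence),
        ("length_association", result.length_assoc),
        ("expression_association", result.expression_assoc),
    ):
        if res is not None:
            scalars[name] = {
                k: (None if pd.isna(v) else v) for k, v in vars(res).items()
            }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(scalars, fh, indent=2, sort_keys=True)
        fh.write("\n")
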