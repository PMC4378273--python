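"""Gene-age assignment from homology hits, age-methylation summaries, and
GO enrichment per phylostratum.

A phylostratum is the phylogenetic node at which a gene's detectable homology
originates; nodes are ordered 1 (cellular organisms, the oldest) to 10 (the
youngest, focal-lineage-specific). A gene is assigned the smallest node
number among the nodes of the species its protein hits; a gene with no hits
outside the focal species belongs to the youngest stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: node names along the focal lineage, oldest to youngest (1..10)
DEFAULT_NODES = (
    "cellular organisms",
    "Eukaryota",
    "Opisthokonta",
    "Metazoa",
    "Eumetazoa",
    "Bilateria",
    "Protostomia",
    "Lophotrochozoa",
    "Mollusca",
    "Bivalvia",
)


@dataclass
class PhylostratumMap:
    """Ordered phylostratum nodes and a species -> node assignment."""

    species_to_node: dict[str, int]
    nodes: tuple[str, ...] = DEFAULT_NODES

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for sp, node in self.species_to_node.items():
            if not 1 <= node <= n:
                raise ValueError(
                    f"species {sp!r} maps to node {node}, outside 1..{n}"
                )

    @property
    def n_strata(self) -> int:
        return len(self.nodes)


def synthetic_phylostratum_map(n_species_per_node: int = 3) -> PhylostratumMap:
    """A synthetic species->node map with named placeholder species, for
    simulations and tests (real maps come from a taxonomy)."""
    mapping = {
        f"node{k:02d}_sp{i + 1}": k
        for k in range(1, len(DEFAULT_NODES) + 1)
        for i in range(n_species_per_node)
    }
    return PhylostratumMap(species_to_node=mapping)


def assign_phylostratum(
    hit_species: list[str] | tuple[str, ...],
    pmap: PhylostratumMap,
    focal_species: str | None = None,
) -> int:
    """Deepest (smallest-numbered) node among the hit species' nodes.

    Self-hits (`focal_species`) are ignored; species absent from the map are
    excluded from the hit set (logged). No informative hit -> the youngest
    stratum.
    """
    nodes = []
    unknown = []
    for sp in hit_species:
        if focal_species is not None and sp == focal_species:
            continue
        node = pmap.species_to_node.get(sp)
        if node is None:
            unknown.append(sp)
        else:
            nodes.append(node)
    if unknown:
        logger.warning(
            "assign_phylostratum: excluded %d unmappable species: %s",
            len(unknown),
            sorted(set(unknown))[:5],
        )
    return min(nodes) if nodes else pmap.n_strata


def assign_phylostrata(
    hits: pd.DataFrame,
    pmap: PhylostratumMap,
    gene_ids,
    focal_species: str | None = None,
) -> pd.Series:
    """Stratum per gene for a hit table (columns gene_id, species).

    Genes of `gene_ids` without any informative hit get the youngest stratum.
    """
    known = hits.copy()
    if focal_species is not None:
        known = known[known["species"] != focal_species]
    mapped = known["species"].map(pmap.species_to_node)
    n_unknown = int(mapped.isna().sum())
    if n_unknown:
        logger.warning(
            "assign_phylostrata: excluded %d hit rows with unmappable species",
            n_unknown,
        )
    known = known.assign(node=mapped).dropna(subset=["node"])
    per_gene = known.groupby("gene_id")["node"].min().astype(int)
    out = pd.Series(pmap.n_strata, index=pd.Index(gene_ids, name="gene_id"))
    out.update(per_gene)
    return out.astype(int).rename("phylostratum")


def methylation_by_age(
    genes: pd.DataFrame,
    min_coverage_fraction: float = 0.70,
) -> pd.DataFrame:
    """Median and quartiles of gene-body methylation per phylostratum.

    Restricted to genes whose CpG coverage fraction meets the threshold and
    whose body level is defined. Empty strata are omitted (logged).
    """
    df = genes.dropna(subset=["level"])
    if "cpg_coverage_fraction" in df.columns:
        df = df[df["cpg_coverage_fraction"] >= min_coverage_fraction]
    rows = []
    present = set()
    for stratum, sub in df.groupby("phylostratum"):
        q1, med, q3 = np.percentile(sub["level"], [25, 50, 75])
        rows.append((int(stratum), len(sub), med, q1, q3))
        present.add(int(stratum))
    missing = set(range(1, 11)) - present
    if missing:
        logger.info("methylation_by_age: empty strata omitted: %s", sorted(missing))
    return pd.DataFrame(
        rows, columns=["phylostratum", "n_genes", "median", "q1", "q3"]
    ).sort_values("phylostratum").reset_index(drop=True)


def go_enrichment(
    stratum_genes,
    background_genes,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term enrichment of a gene set against background genes.

    For every GO term annotated to at least one background gene, a 2x2 table
    (stratum vs non-stratum background, with vs without the term) is tested
    with a one-sided Fisher exact test (enrichment) and a chi-square test;
    Fisher p-values are BH-adjusted across the stratum's terms and a term is
    significant when its adjusted value falls below `alpha`.
    """
    stratum = set(stratum_genes)
    background = set(background_genes)
    if not stratum <= background:
        raise ValueError("background must contain every stratum gene")
    ann = annotation[annotation["gene_id"].isin(background)]
    if ann.empty:
        raise ValueError("annotation covers no background gene")
    n_s = len(stratum)
    n_b = len(background)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        genes_with = set(sub["gene_id"])
        a = len(genes_with & stratum)  # stratum, with term
        b = n_s - a  # stratum, without
        c = len(genes_with) - a  # non-stratum background, with term
        d = (n_b - n_s) - c  # non-stratum background, without
        _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2_p = float(stats.chi2_contingency(table)[1])
        else:
            chi2_p = float("nan")
        rows.append((term, a, n_s, len(genes_with), n_b, float(fisher_p), chi2_p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "stratum_with_term",
            "stratum_total",
            "background_with_term",
            "background_total",
            "fisher_p",
            "chi2_p",
        ],
    )
    out["q_value"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < alpha
    return out.sort_values(["q_value", "term"]).reset_index(drop=True)
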