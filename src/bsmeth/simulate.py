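"""Synthetic BS-seq data generator.

Produces a miniature annotated genome (genes with exon/intron/UTR structure,
eight repeat classes carrying divergence rates, a few ncRNAs, and an
unmethylated spike-in contig playing the role of the lambda control DNA), a
ground-truth methylome with the statistical structure a mollusc-type mosaic
methylome shows, and post-alignment bisulfite read stacks.

Structure emulated by the methylome:

* methylation is almost exclusively CpG (controlled by
  ``cpg_fraction_of_methylation``, default > 99%);
* gene bodies carry mosaic methylation whose density follows the gene's
  expression rank (unimodal in rank: moderately expressed genes are the most
  methylated, with a dip for the top decile) modulated by gene age
  (phylostratum), peaking for genes of phylostratum 2;
* repeat methylation decays with divergence from the consensus (young repeats
  are the methylated ones);
* the spike-in contig is fully unmethylated, so observed C reads on it arise
  only from the error rate (non-conversion plus T/C sequencing error).

Read stacks are generated directly at the post-alignment contract: reads of
``read_length`` bp are placed per strand at the requested mean depth; each
read observes C at a cytosine of true level *m* with probability
``m + (1 - m) * e``. A configurable fraction of PCR-duplicate read starts and
sub-threshold base qualities is injected so the filtering stage has work to do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import gene_subfeatures  # noqa: F401  (public via this module too)
from .reference import enumerate_cytosines

logger = logging.getLogger(__name__)

REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "DNA",
    "helitron",
    "satellite",
    "simple",
    "tandem",
)

NCRNA_KINDS = ("tRNA", "snRNA", "rRNA")

SPIKE_CHROM = "spike"

#: default mean gene-body CpG methylation density by expression rank
#: (0 = silent, 1..10 = expression deciles). Unimodal with the most
#: methylation at moderate-to-high expression and a dip for the top decile.
DEFAULT_LEVEL_BY_RANK = {
    0: 0.02,
    1: 0.05,
    2: 0.12,
    3: 0.22,
    4: 0.32,
    5: 0.42,
    6: 0.52,
    7: 0.60,
    8: 0.64,
    9: 0.58,
    10: 0.35,
}

#: gene-body CpG methylation density by phylostratum (1..10): a clear peak
#: at phylostratum 2 (genes originating with eukaryotes), declining toward
#: the youngest lineage-specific genes. Combined with the rank component as
#: an equal-weight average, so both marginal gradients stay recoverable.
DEFAULT_LEVEL_BY_AGE = {
    1: 0.35,
    2: 0.85,
    3: 0.45,
    4: 0.40,
    5: 0.35,
    6: 0.30,
    7: 0.25,
    8: 0.18,
    9: 0.12,
    10: 0.08,
}


@dataclass
class SimGenomeSpec:
    """Layout of the simulated genome."""

    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 80
    exons_per_gene: int = 4
    n_repeats_per_class: int = 6
    n_ncrnas_per_kind: int = 3
    spike_in_length: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("n_chroms and chrom_length must be >= 1")
        if self.exons_per_gene < 1:
            raise ValueError("exons_per_gene must be >= 1")
        if min(self.n_genes, self.n_repeats_per_class, self.n_ncrnas_per_kind) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.spike_in_length < 800:
            # a random-base contig of 800 bp carries ~400 cytosines; shorter
            # contigs risk violating the >= 200 cytosine requirement
            raise ValueError("spike_in_length must be >= 800 bp")


@dataclass
class SimMethylomeSpec:
    """Statistical parameters of the simulated methylome and read stacks."""

    error_rate: float = 0.004  # non-conversion + T/C sequencing error
    depth_mean: float = 12.0  # mean read depth per strand
    gene_body_level_by_rank: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_BY_RANK)
    )
    gene_body_level_by_age: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_BY_AGE)
    )
    repeat_level_at_zero: float = 0.70  # CpG methylation density of a fresh repeat
    repeat_level_decay: float = 6.0  # e-folding per unit divergence
    background_level: float = 0.02  # density outside genes/repeats
    cpg_fraction_of_methylation: float = 0.995
    silent_fraction: float = 0.15  # genes with RPKM = 0
    read_length: int = 90
    duplicate_fraction: float = 0.02  # PCR-duplicate read starts
    low_quality_fraction: float = 0.05  # bases with phred < 30
    other_base_fraction: float = 0.002  # non-C/T observations

    def validate(self) -> None:
        for name in (
            "error_rate",
            "repeat_level_at_zero",
            "background_level",
            "cpg_fraction_of_methylation",
            "silent_fraction",
            "duplicate_fraction",
            "low_quality_fraction",
            "other_base_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gene_body_level_by_rank", "gene_body_level_by_age"):
            for key, lvl in getattr(self, name).items():
                if not 0.0 <= lvl <= 1.0:
                    raise ValueError(f"{name}[{key}] outside [0, 1]")
        if self.repeat_level_decay < 0:
            raise ValueError("repeat_level_decay must be >= 0 (level non-increasing)")
        if self.depth_mean <= 0 or self.read_length < 1:
            raise ValueError("depth_mean and read_length must be positive")


@dataclass
class SimGenome:
    """In-memory simulated genome bundle."""

    sequences: dict[str, str]  # includes the spike-in contig
    genes: pd.DataFrame  # gene_id chrom start end strand utr5_len utr3_len
    exons: pd.DataFrame  # gene_id exon_index start end
    repeats: pd.DataFrame  # repeat_id chrom start end strand rclass divergence
    ncrnas: pd.DataFrame  # ncrna_id chrom start end strand kind
    spike_chrom: str
    spec: SimGenomeSpec

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class TruthTable:
    """Ground truth for recovery testing.

    ``sites`` holds one row per strand-specific cytosine of the genome
    (spike-in included) with its true methylation level; ``genes`` and
    ``repeats`` carry per-feature truth (body level, expression, phylostratum;
    repeat level and divergence).
    """

    sites: pd.DataFrame  # chrom pos strand context context_complete true_level
    genes: pd.DataFrame  # gene_id ... rpkm rank phylostratum true_body_level
    repeats: pd.DataFrame  # repeat_id rclass divergence true_level


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _gene_structure(
    rng: np.random.Generator, start: int, length: int, n_exons: int
) -> tuple[list[tuple[int, int]], int, int]:
    """Exon intervals (genomic, ascending) and UTR lengths for one gene."""
    if n_exons == 1:
        exons = [(start, start + length)]
    else:
        intron_total = max(n_exons - 1, int(0.3 * length))
        exon_total = length - intron_total
        w = rng.dirichlet(np.full(n_exons, 4.0))
        exon_lens = np.maximum(1, (w * exon_total).astype(int))
        wi = rng.dirichlet(np.full(n_exons - 1, 4.0))
        intron_lens = np.maximum(1, (wi * intron_total).astype(int))
        exons = []
        cur = start
        for i in range(n_exons):
            exons.append((cur, cur + int(exon_lens[i])))
            cur += int(exon_lens[i])
            if i < n_exons - 1:
                cur += int(intron_lens[i])
        # stretch the last exon so the gene spans exactly `length`
        last_s, last_e = exons[-1]
        exons[-1] = (last_s, start + length)
    first_len = exons[0][1] - exons[0][0]
    last_len = exons[-1][1] - exons[-1][0]
    utr5 = min(100, max(0, first_len - 40))
    utr3 = min(150, max(0, last_len - 40))
    return exons, utr5, utr3


def simulate_genome(spec: SimGenomeSpec) -> SimGenome:
    """Generate the annotated genome. Deterministic under ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    sequences = {c: _random_sequence(rng, spec.chrom_length) for c in chroms}
    spike_seq = _random_sequence(rng, spec.spike_in_length)
    n_cyt = spike_seq.count("C") + spike_seq.count("G")
    if n_cyt < 200:
        raise ValueError(
            f"spike-in contig must contain >= 200 cytosines, got {n_cyt}; "
            "increase spike_in_length"
        )
    sequences[SPIKE_CHROM] = spike_seq

    # build the feature request list, then lay features out left to right per
    # chromosome with random intergenic gaps; non-overlap holds across all
    # feature classes so element precedence is unambiguous
    requests: list[tuple[str, str, int]] = []  # (kind_tag, name, length)
    for i in range(spec.n_genes):
        requests.append(("gene", f"g{i + 1:04d}", int(rng.integers(800, 2501))))
    rep_len = {
        "SINE": (150, 400),
        "LINE": (300, 700),
        "LTR": (250, 600),
        "DNA": (200, 500),
        "helitron": (200, 500),
        "satellite": (100, 300),
        "simple": (60, 200),
        "tandem": (60, 200),
    }
    r_i = 0
    for rclass in REPEAT_CLASSES:
        lo, hi = rep_len[rclass]
        for _ in range(spec.n_repeats_per_class):
            r_i += 1
            requests.append((f"repeat:{rclass}", f"r{r_i:04d}", int(rng.integers(lo, hi))))
    n_i = 0
    for kind in NCRNA_KINDS:
        for _ in range(spec.n_ncrnas_per_kind):
            n_i += 1
            requests.append((f"ncrna:{kind}", f"n{n_i:03d}", int(rng.integers(70, 200))))

    # intergenic gaps scale with the free space so any feature set that fits
    # the genome places successfully; 60% of the spare is spent on gaps
    total_len = sum(length for _, _, length in requests)
    space = spec.n_chroms * spec.chrom_length
    if requests and total_len >= space:
        raise ValueError(
            "chrom_length too small to place requested features: "
            f"{total_len} bp of features exceed {space} bp of genome; "
            "increase chrom_length or reduce "
            "n_genes/n_repeats_per_class/n_ncrnas_per_kind"
        )
    mean_gap = 0.6 * (space - total_len) / max(len(requests), 1)
    gap_lo = min(600, max(20, int(0.25 * mean_gap)))
    gap_hi = max(gap_lo + 1, min(2400, int(1.75 * mean_gap)))

    order = rng.permutation(len(requests))
    cursors = {c: 0 for c in chroms}
    placed: list[tuple[str, str, str, int, int]] = []  # tag name chrom start end
    ci = 0
    for idx in order:
        tag, name, length = requests[idx]
        placed_ok = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            gap = int(rng.integers(gap_lo, gap_hi))
            start = cursors[chrom] + gap
            if start + length <= spec.chrom_length:
                cursors[chrom] = start + length
                placed.append((tag, name, chrom, start, start + length))
                placed_ok = True
                break
        if not placed_ok:
            raise ValueError(
                "chrom_length too small to place requested features: "
                f"failed at {tag} {name} (length {length}); increase chrom_length "
                "or reduce n_genes/n_repeats_per_class/n_ncrnas_per_kind"
            )

    gene_rows, exon_rows, rep_rows, nc_rows = [], [], [], []
    for tag, name, chrom, start, end in placed:
        strand = "+" if rng.random() < 0.5 else "-"
        if tag == "gene":
            exons, utr5, utr3 = _gene_structure(
                rng, start, end - start, spec.exons_per_gene
            )
            gene_rows.append((name, chrom, start, end, strand, utr5, utr3))
            for k, (es, ee) in enumerate(exons):
                exon_rows.append((name, k, es, ee))
        elif tag.startswith("repeat:"):
            rep_rows.append(
                (name, chrom, start, end, strand, tag.split(":", 1)[1],
                 round(float(rng.uniform(0.0, 0.5)), 4))
            )
        else:
            nc_rows.append((name, chrom, start, end, strand, tag.split(":", 1)[1]))

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "utr5_len", "utr3_len"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    exons = pd.DataFrame(
        exon_rows, columns=["gene_id", "exon_index", "start", "end"]
    ).sort_values(["gene_id", "exon_index"]).reset_index(drop=True)
    repeats = pd.DataFrame(
        rep_rows,
        columns=["repeat_id", "chrom", "start", "end", "strand", "rclass", "divergence"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    ncrnas = pd.DataFrame(
        nc_rows, columns=["ncrna_id", "chrom", "start", "end", "strand", "kind"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    return SimGenome(
        sequences=sequences,
        genes=genes,
        exons=exons,
        repeats=repeats,
        ncrnas=ncrnas,
        spike_chrom=SPIKE_CHROM,
        spec=spec,
    )


def simulate_methylome(
    genome: SimGenome, spec: SimMethylomeSpec | None = None, seed: int | None = None
) -> TruthTable:
    """Assign a true methylation level to every cytosine of the genome."""
    spec = spec if spec is not None else SimMethylomeSpec()
    spec.validate()
    rng = np.random.default_rng(
        genome.spec.seed + 1_000_003 if seed is None else seed
    )

    sites = enumerate_cytosines(genome.sequences)
    level = np.zeros(len(sites), dtype=float)
    is_cpg = (sites["context"] == "CpG").to_numpy()
    on_spike = (sites["chrom"] == genome.spike_chrom).to_numpy()

    genes = genome.genes.copy()
    n_genes = len(genes)

    # expression: a silent fraction at RPKM 0, the rest lognormal; ranks are
    # expression deciles computed exactly as the analysis side computes them
    if n_genes:
        silent = rng.random(n_genes) < spec.silent_fraction
        rpkm = np.where(silent, 0.0, np.round(rng.lognormal(1.5, 1.2, n_genes), 4))
        genes["rpkm"] = rpkm
        from .profiles import rank_genes  # local import to avoid a cycle

        ranks = rank_genes(genes[["gene_id", "rpkm"]], k=10)
        genes = genes.merge(ranks[["gene_id", "rank"]], on="gene_id")
        # phylostrata cycled over shuffled genes: every stratum is populated
        strata = np.tile(np.arange(1, 11), n_genes // 10 + 1)[:n_genes]
        genes["phylostratum"] = strata[rng.permutation(n_genes)]
    else:
        genes["rpkm"] = pd.Series(dtype=float)
        genes["rank"] = pd.Series(dtype=int)
        genes["phylostratum"] = pd.Series(dtype=int)

    def mosaic(mask: np.ndarray, density: float) -> None:
        idx = np.flatnonzero(mask)
        chosen = idx[rng.random(len(idx)) < density]
        level[chosen] = rng.uniform(0.80, 1.0, len(chosen))

    covered = np.zeros(len(sites), dtype=bool)  # CpGs claimed by a feature
    body_levels = []
    for g in genes.itertuples(index=False):
        gmask = (
            is_cpg
            & (sites["chrom"] == g.chrom).to_numpy()
            & (sites["pos"].to_numpy() >= g.start)
            & (sites["pos"].to_numpy() < g.end)
        )
        density = np.clip(
            0.5 * spec.gene_body_level_by_rank.get(int(g.rank), 0.0)
            + 0.5 * spec.gene_body_level_by_age.get(int(g.phylostratum), 0.0),
            0.0,
            0.95,
        )
        mosaic(gmask, float(density))
        covered |= gmask
        body_levels.append(float(level[gmask].mean()) if gmask.any() else np.nan)
    genes["true_body_level"] = body_levels
    genes["length"] = genes["end"] - genes["start"]

    rep_out = genome.repeats.copy()
    rep_levels = []
    for r in rep_out.itertuples(index=False):
        rmask = (
            is_cpg
            & (sites["chrom"] == r.chrom).to_numpy()
            & (sites["pos"].to_numpy() >= r.start)
            & (sites["pos"].to_numpy() < r.end)
        )
        density = spec.repeat_level_at_zero * float(
            np.exp(-spec.repeat_level_decay * r.divergence)
        )
        mosaic(rmask, density)
        covered |= rmask
        rep_levels.append(float(level[rmask].mean()) if rmask.any() else np.nan)
    rep_out["true_level"] = rep_levels

    # background CpGs (outside genes and repeats, off the spike-in)
    bg = is_cpg & ~covered & ~on_spike
    mosaic(bg, spec.background_level)

    # non-CpG methylation: sized so the CpG share of methylated sites matches
    # cpg_fraction_of_methylation; zero when the fraction is 1
    n_mcpg = int(((level > 0) & is_cpg).sum())
    f = spec.cpg_fraction_of_methylation
    if f < 1.0 and n_mcpg > 0:
        target = int(round(n_mcpg * (1.0 - f) / f))
        cand = np.flatnonzero(~is_cpg & ~on_spike & (level == 0))
        chosen = rng.choice(cand, size=min(target, len(cand)), replace=False)
        level[chosen] = rng.uniform(0.80, 1.0, len(chosen))

    level[on_spike] = 0.0
    out_sites = sites.copy()
    out_sites["true_level"] = level
    return TruthTable(sites=out_sites, genes=genes, repeats=rep_out)


def simulate_read_stacks(
    genome: SimGenome,
    truth: TruthTable,
    spec: SimMethylomeSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Post-alignment read stack for the whole genome.

    One row per (read, covered cytosine): columns ``chrom, pos, strand,
    observed_base, base_quality, read_start, read_id``.
    """
    spec = spec if spec is not None else SimMethylomeSpec()
    spec.validate()
    rng = np.random.default_rng(
        genome.spec.seed + 2_000_003 if seed is None else seed
    )
    e = spec.error_rate
    rl = spec.read_length

    # per (chrom, strand): sorted cytosine positions and their true levels
    tr = truth.sites
    parts = []
    read_id0 = 0
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        sub_c = tr[tr["chrom"] == chrom]
        for strand in ("+", "-"):
            sub = sub_c[sub_c["strand"] == strand].sort_values("pos")
            P = sub["pos"].to_numpy(np.int64)
            M = sub["true_level"].to_numpy(float)
            n_reads = int(round(spec.depth_mean * L / rl))
            if n_reads == 0 or len(P) == 0:
                continue
            starts = rng.integers(0, max(1, L - rl + 1), n_reads)
            n_dup = int(round(spec.duplicate_fraction * n_reads))
            if n_dup:
                starts = np.concatenate(
                    [starts, rng.choice(starts, n_dup, replace=True)]
                )
            starts = np.sort(starts, kind="mergesort")
            n_tot = len(starts)
            rids = read_id0 + np.arange(n_tot, dtype=np.int64)
            read_id0 += n_tot

            lo = np.searchsorted(P, starts)
            hi = np.searchsorted(P, starts + rl)
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            cum = np.cumsum(counts) - counts
            site_idx = np.repeat(lo - cum, counts) + np.arange(total)
            pos = P[site_idx]
            m = M[site_idx]
            obs_c = rng.random(total) < (m + (1.0 - m) * e)
            base = np.where(obs_c, "C", "T").astype(object)
            other = rng.random(total) < spec.other_base_fraction
            if other.any():
                base[other] = np.where(rng.random(int(other.sum())) < 0.5, "A", "G")
            qual = rng.integers(30, 42, total)
            low = rng.random(total) < spec.low_quality_fraction
            if low.any():
                qual[low] = rng.integers(2, 30, int(low.sum()))
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "observed_base": base,
                        "base_quality": qual,
                        "read_start": np.repeat(starts, counts),
                        "read_id": np.repeat(rids, counts),
                    }
                )
            )
    if not parts:
        return pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "strand",
                "observed_base",
                "base_quality",
                "read_start",
                "read_id",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def simulate_hit_table(
    truth_genes: pd.DataFrame, pmap, seed: int = 0
) -> pd.DataFrame:
    """Homology hit table consistent with the genes' true phylostrata.

    Each gene receives one hit in a species of its own stratum's node plus
    optional hits in younger (higher-numbered) nodes, so the minimum-node
    assignment rule recovers the truth exactly.
    """
    rng = np.random.default_rng(seed)
    by_node: dict[int, list[str]] = {}
    for sp, node in pmap.species_to_node.items():
        by_node.setdefault(node, []).append(sp)
    for node in by_node:
        by_node[node].sort()
    rows = []
    for g in truth_genes.itertuples(index=False):
        s = int(g.phylostratum)
        rows.append((g.gene_id, by_node[s][int(rng.integers(len(by_node[s])))]))
        for extra_node in range(s + 1, 11):
            if rng.random() < 0.4 and extra_node in by_node:
                sp = by_node[extra_node][int(rng.integers(len(by_node[extra_node])))]
                rows.append((g.gene_id, sp))
    return pd.DataFrame(rows, columns=["gene_id", "species"])


def simulate_go_annotation(
    truth_genes: pd.DataFrame, n_terms: int = 30, terms_per_gene: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random GO annotation: each gene draws a Poisson number of terms."""
    rng = np.random.default_rng(seed)
    terms = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    rows = []
    for g in truth_genes.itertuples(index=False):
        k = min(n_terms, 1 + rng.poisson(max(terms_per_gene - 1, 0)))
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append((g.gene_id, terms[int(t)]))
    return pd.DataFrame(rows, columns=["gene_id", "term"])
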