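"""Readers and writers for every external format the pipeline touches.

Dialects, fixed bit-exact for round trips:

* genome FASTA (Biopython; spike-in contig included);
* genes GFF3, 1-based inclusive coordinates per the standard, holding gene /
  mRNA / exon / CDS / five_prime_UTR / three_prime_UTR rows (internal
  coordinates are 0-based half-open; the shift happens only at this border);
* repeat BED, 0-based half-open: chrom, start, end, class (col 4),
  divergence rate (col 5), strand, repeat_id;
* ncRNA BED: chrom, start, end, kind, 0, strand, ncrna_id;
* tab-separated tables with a header row: cytosine counts
  (chrom, pos, strand, context, c_count, depth), read stacks
  (chrom, pos, strand, observed_base, base_quality, read_start, read_id),
  expression (gene_id, rpkm), homology hits (gene_id, species), GO
  annotation (gene_id, term), species->node map (species, node).

Malformed lines raise ``ValueError`` naming the file and line number; a BED
record with a non-numeric divergence is skipped and counted
(``df.attrs["n_rejected"]``) rather than aborting the run. Output tables
carry the configuration hash on a leading comment line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import gene_subfeatures

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path: str | Path) -> None:
    """Emit gene models as GFF3 (1-based inclusive)."""
    sub = gene_subfeatures(genes, exons)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            attrs = (
                f"ID={g.gene_id};utr5_len={g.utr5_len};utr3_len={g.utr3_len}"
            )
            fh.write(
                f"{g.chrom}\tbsmeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tbsmeth\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for e in (
                exons[exons["gene_id"] == g.gene_id]
                .sort_values("exon_index")
                .itertuples(index=False)
            ):
                fh.write(
                    f"{g.chrom}\tbsmeth\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id}.t1\n"
                )
            kinds = {"CDS": "CDS", "UTR5": "five_prime_UTR", "UTR3": "three_prime_UTR"}
            sg = sub[(sub["gene_id"] == g.gene_id) & sub["kind"].isin(kinds)]
            for f in sg.sort_values(["start", "kind"]).itertuples(index=False):
                fh.write(
                    f"{g.chrom}\tbsmeth\t{kinds[f.kind]}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id}.t1\n"
                )


def read_gff3(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse gene and exon rows back to internal 0-based half-open tables."""
    gene_rows, exon_rows = [], []
    exon_counter: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns, "
                    f"got {len(fields)}"
                )
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gene_rows.append(
                    (
                        attr["ID"],
                        chrom,
                        start_i,
                        end_i,
                        strand,
                        int(attr.get("utr5_len", 0)),
                        int(attr.get("utr3_len", 0)),
                    )
                )
            elif ftype == "exon":
                gene_id = attr["Parent"].rsplit(".t1", 1)[0]
                idx = exon_counter.get(gene_id, 0)
                exon_counter[gene_id] = idx + 1
                exon_rows.append((gene_id, idx, start_i, end_i))
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "utr5_len", "utr3_len"],
    )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "exon_index", "start", "end"])
    return genes, exons


# ---------------------------------------------------------------- BED

def write_repeat_bed(repeats: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.rclass}\t{r.divergence}\t"
                f"{r.strand}\t{r.repeat_id}\n"
            )


def read_repeat_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 BED columns, got {len(fields)}"
                )
            chrom, start, end, rclass, div, strand, rid = fields
            try:
                start_i, end_i = int(start), int(end)
                div_f = float(div)
            except ValueError:
                n_rejected += 1
                logger.warning(
                    "%s: line %d: rejected repeat record (bad coordinates or "
                    "divergence %r)", path, lineno, div,
                )
                continue
            rows.append((rid, chrom, start_i, end_i, strand, rclass, div_f))
    out = pd.DataFrame(
        rows,
        columns=["repeat_id", "chrom", "start", "end", "strand", "rclass", "divergence"],
    )
    out.attrs["n_rejected"] = n_rejected
    return out


def write_ncrna_bed(ncrnas: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ncrnas.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t0\t{r.strand}\t{r.ncrna_id}\n"
            )


def read_ncrna_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 BED columns, got {len(fields)}"
                )
            chrom, start, end, kind, _, strand, nid = fields
            try:
                rows.append((nid, chrom, int(start), int(end), strand, kind))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
    return pd.DataFrame(
        rows, columns=["ncrna_id", "chrom", "start", "end", "strand", "kind"]
    )


# ---------------------------------------------------------------- TSV tables

_TSV_SCHEMAS: dict[str, tuple[tuple[str, type], ...]] = {
    "sites": (
        ("chrom", str),
        ("pos", int),
        ("strand", str),
        ("context", str),
        ("c_count", int),
        ("depth", int),
    ),
    "stack": (
        ("chrom", str),
        ("pos", int),
        ("strand", str),
        ("observed_base", str),
        ("base_quality", int),
        ("read_start", int),
        ("read_id", int),
    ),
    "expression": (("gene_id", str), ("rpkm", float)),
    "hits": (("gene_id", str), ("species", str)),
    "go": (("gene_id", str), ("term", str)),
    "species_map": (("species", str), ("node", int)),
}


def _write_tsv(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    cols = [c for c, _ in _TSV_SCHEMAS[schema]]
    df[cols].to_csv(path, sep="\t", index=False)


def _read_tsv(path: str | Path, schema: str) -> pd.DataFrame:
    spec = _TSV_SCHEMAS[schema]
    cols = [c for c, _ in spec]
    dtypes = {c: (np.int64 if t is int else (float if t is float else str)) for c, t in spec}
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes)
    except (ValueError, pd.errors.ParserError):
        # locate the first offending line for the error message
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(header):
                    raise ValueError(
                        f"{path}: line {lineno}: expected {len(header)} columns, "
                        f"got {len(fields)}"
                    ) from None
                for (col, typ), val in zip(spec, fields):
                    try:
                        typ(val)
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: bad value {val!r} "
                            f"for column {col}"
                        ) from None
        raise
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[cols]


def write_site_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(sites, path, "sites")


def read_site_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, "sites")


def write_stack_tsv(stack: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(stack, path, "stack")


def read_stack_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, "stack")


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(expr, path, "expression")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, "expression")


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(hits, path, "hits")


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, "hits")


def write_go_tsv(go: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(go, path, "go")


def read_go_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, "go")


def write_species_map_tsv(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path, "species_map")


def read_species_map_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, "species_map")


# ---------------------------------------------------------------- outputs

def write_output_table(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """TSV output stamped with the configuration hash on a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_output_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------- bundles

def write_genome_bundle(genome, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + GFF3 + repeat/ncRNA BED for a simulated genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": outdir / "genome.fasta",
        "genes_gff3": outdir / "genes.gff3",
        "repeats_bed": outdir / "repeats.bed",
        "ncrna_bed": outdir / "ncrna.bed",
    }
    write_fasta(genome.sequences, paths["genome_fasta"])
    write_gff3(genome.genes, genome.exons, paths["genes_gff3"])
    write_repeat_bed(genome.repeats, paths["repeats_bed"])
    write_ncrna_bed(genome.ncrnas, paths["ncrna_bed"])
    return paths
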