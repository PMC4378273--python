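"""Pipeline configuration: paths, analysis thresholds and their valid ranges.

The threshold defaults are the analysis' operating point: FDR alpha 0.01 for
methylcytosine calling, phred >= 30 base filter, >= 5X depth for site levels,
>= 2X coverage denominators, >= 70% gene CpG coverage for gene analyses,
>= 2 mCGs to class a feature methylated, 1-kb density windows, 2-kb flanks,
10 expression ranks, enrichment alpha 0.05, top-20% expression exclusion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input/output paths
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    repeats_bed: str | None = None
    ncrna_bed: str | None = None
    stack_tsv: str | None = None
    expression_tsv: str | None = None
    hits_tsv: str | None = None
    go_tsv: str | None = None
    species_map_tsv: str | None = None
    outdir: str | None = None
    spike_chrom: str = "spike"
    focal_species: str | None = None
    error_rate: float | None = None  # override; otherwise spike-estimated

    # thresholds (defaults are the analysis' printed operating point)
    alpha: float = 0.01
    min_quality: int = 30
    level_min_depth: int = 5
    coverage_min_depth: int = 2
    gene_coverage_fraction: float = 0.70
    methylated_min_mcgs: int = 2
    window: int = 1000
    flank: int = 2000
    rank_bins: int = 10
    enrichment_alpha: float = 0.05
    exclude_top_fraction: float = 0.2

    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.enrichment_alpha < 1.0:
            raise ValueError("enrichment_alpha must lie in (0, 1)")
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")
        if self.level_min_depth < 1 or self.coverage_min_depth < 1:
            raise ValueError("depth thresholds must be >= 1")
        if not 0.0 <= self.gene_coverage_fraction <= 1.0:
            raise ValueError("gene_coverage_fraction must lie in [0, 1]")
        if self.methylated_min_mcgs < 1:
            raise ValueError("methylated_min_mcgs must be >= 1")
        if self.window < 1 or self.flank < 0 or self.rank_bins < 1:
            raise ValueError("window/flank/rank_bins out of range")
        if not 0.0 <= self.exclude_top_fraction < 1.0:
            raise ValueError("exclude_top_fraction must lie in [0, 1)")
        if self.error_rate is not None and not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate override must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):  # allow paths:/thresholds: sections
                flat.update(value)
            else:
                flat[key] = value
        unknown = set(flat) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**flat)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Stable digest of the full configuration, stamped on every output."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
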