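"""Recovery benchmarks run against the generator's ground truth.

The central one measures the empirical false discovery rate of the binomial
caller: simulate ~100,000 cytosines of which 10% are truly methylated at
level 0.8, cover them at ~12 reads per strand with a 0.4% error rate,
estimate the error rate from the unmethylated spike-in exactly as the
pipeline does, call methylation at the default FDR threshold, and report the
fraction of called sites whose true level was zero, pooled over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import call_methylation
from .reference import enumerate_cytosines
from .simulate import (
    SimGenomeSpec,
    SimMethylomeSpec,
    TruthTable,
    simulate_genome,
    simulate_read_stacks,
)
from .sites import estimate_error_rate, filter_read_stack, pile_counts


@dataclass(frozen=True)
class FdrBenchmarkResult:
    empirical_fdr: float  # fraction of called sites simulated unmethylated
    n_sites: int  # simulated cytosines, pooled over replicates
    n_called: int
    n_false: int
    n_true_methylated: int
    power: float  # fraction of truly methylated sites called


def empirical_fdr_benchmark(
    seeds,
    chrom_length: int = 200_000,
    methylated_fraction: float = 0.10,
    true_level: float = 0.8,
    depth_mean: float = 12.0,
    error_rate: float = 0.004,
    alpha: float = 0.01,
) -> FdrBenchmarkResult:
    """Pooled empirical FDR of the caller over seeded replicates.

    Each replicate simulates one featureless chromosome (~``chrom_length/2``
    strand-specific cytosines) plus a spike-in contig, marks a random
    `methylated_fraction` of the chromosomal sites at `true_level`, generates
    read stacks at `depth_mean` per strand, runs filtering, pileup, spike-in
    error-rate estimation and calling at `alpha`, and scores calls against
    the truth.
    """
    n_called = n_false = n_true = n_recovered = n_sites = 0
    for seed in seeds:
        gspec = SimGenomeSpec(
            n_chroms=1,
            chrom_length=chrom_length,
            n_genes=0,
            n_repeats_per_class=0,
            n_ncrnas_per_kind=0,
            seed=int(seed),
        )
        genome = simulate_genome(gspec)
        rng = np.random.default_rng(int(seed) + 500_009)
        sites = enumerate_cytosines(genome.sequences)
        level = np.where(
            (sites["chrom"] != genome.spike_chrom).to_numpy()
            & (rng.random(len(sites)) < methylated_fraction),
            true_level,
            0.0,
        )
        truth = TruthTable(
            sites=sites.assign(true_level=level),
            genes=pd.DataFrame(),
            repeats=pd.DataFrame(),
        )
        mspec = SimMethylomeSpec(error_rate=error_rate, depth_mean=depth_mean)
        stack = simulate_read_stacks(genome, truth, mspec, seed=int(seed) + 900_001)
        piled = pile_counts(filter_read_stack(stack), genome.sequences)
        est = estimate_error_rate(piled, spike_chrom=genome.spike_chrom)
        calls = call_methylation(piled, est.error_rate, alpha=alpha)

        truth_map = truth.sites.set_index(["chrom", "pos", "strand"])["true_level"]
        called = calls[calls["is_methylated"]]
        true_at_called = truth_map.loc[
            list(zip(called["chrom"], called["pos"], called["strand"]))
        ].to_numpy()
        on_chrom = truth.sites["chrom"] != genome.spike_chrom
        n_sites += int(on_chrom.sum())
        n_called += len(called)
        n_false += int((true_at_called == 0).sum())
        n_true += int((level > 0).sum())

        meth_keys = truth.sites.loc[level > 0, ["chrom", "pos", "strand"]]
        called_keys = set(zip(called["chrom"], called["pos"], called["strand"]))
        n_recovered += sum(
            k in called_keys
            for k in zip(meth_keys["chrom"], meth_keys["pos"], meth_keys["strand"])
        )
    return FdrBenchmarkResult(
        empirical_fdr=n_false / n_called if n_called else 0.0,
        n_sites=n_sites,
        n_called=n_called,
        n_false=n_false,
        n_true_methylated=n_true,
        power=n_recovered / n_true if n_true else float("nan"),
    )
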