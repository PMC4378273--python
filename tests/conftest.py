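import numpy as np
import pandas as pd
import pytest

from bsmeth import (
    SimGenomeSpec,
    SimMethylomeSpec,
    add_site_levels,
    call_methylation,
    enumerate_cytosines,
    estimate_error_rate,
    filter_read_stack,
    pile_counts,
    simulate_genome,
    simulate_methylome,
    simulate_read_stacks,
)


@pytest.fixture(scope="session")
def tiny_genome_spec():
    return SimGenomeSpec(
        n_chroms=1,
        chrom_length=70_000,
        n_genes=8,
        n_repeats_per_class=1,
        n_ncrnas_per_kind=1,
        spike_in_length=4_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_genome_spec):
    return simulate_genome(tiny_genome_spec)


@pytest.fixture(scope="session")
def tiny_run(tiny_genome):
    """Full small simulation: truth, stack, filtered sites, calls, levels."""
    mspec = SimMethylomeSpec()
    truth = simulate_methylome(tiny_genome, mspec)
    stack = simulate_read_stacks(tiny_genome, truth, mspec)
    filtered = filter_read_stack(stack)
    sites = pile_counts(filtered, tiny_genome.sequences)
    est = estimate_error_rate(sites, spike_chrom=tiny_genome.spike_chrom)
    calls = call_methylation(sites, est.error_rate)
    return {
        "genome": tiny_genome,
        "truth": truth,
        "stack": stack,
        "filtered": filtered,
        "sites": sites,
        "error": est,
        "calls": calls,
        "site_levels": add_site_levels(calls),
        "ref_sites": enumerate_cytosines(tiny_genome.sequences),
    }


def make_stack(rows):
    """Build a read-stack frame from (chrom,pos,strand,base,qual,start,rid)."""
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "strand",
            "observed_base",
            "base_quality",
            "read_start",
            "read_id",
        ],
    )


def make_sites(rows):
    """Build a site table from (chrom,pos,strand,context,c_count,depth)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "c_count", "depth"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
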