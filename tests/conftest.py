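"""Shared fixtures: small simulated datasets generated at test time."""

import pandas as pd
import pytest

from bsmeth import core, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=1, n_chroms=2, chrom_len=30_000, n_genes=10, n_repeats=10
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genome, annotation, and one simulated sample with called sites."""
    genome, ann = simulate.simulate_genome(small_config)
    sites, truth = simulate.simulate_methylome(genome, ann, small_config, "petal")
    called = core.call_methylated_sites(sites)
    return {
        "config": small_config,
        "genome": genome,
        "ann": ann,
        "sites": sites,
        "truth": truth,
        "called": called,
    }


def make_sites(rows):
    """Build a CX-style site frame from (chrom, pos, strand, m, u, context) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count_meth", "count_unmeth", "context"],
    ).assign(trinucleotide="CNN")
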