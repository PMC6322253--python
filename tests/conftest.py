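import numpy as np
import pandas as pd
import pytest

from gbmeth import simulate


def make_allc(rows):
    """Build an allc frame from (chrom, pos, strand, context, mc, n) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "mc", "n"]
    )


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(
        seed=11,
        n_chrom=1,
        chrom_len=250_000,
        n_genes=60,
        gene_len_range=(1_000, 2_500),
        depth_mean=20.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One fully simulated study shared by read-only tests."""
    return simulate.simulate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
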