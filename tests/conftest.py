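import numpy as np
import pandas as pd
import pytest

from crossmeth import simulate
from crossmeth.io import SampleKey, SampleTable


@pytest.fixture(scope="session")
def small_catalogue():
    _, cat = simulate.simulate_genome(1, 5000, seed=100)
    return cat


@pytest.fixture(scope="session")
def sim_sample(small_catalogue):
    key = SampleKey("sim", "root", "control23", 1)
    tables, truth = simulate.simulate_methylome(
        small_catalogue, mean_cov=15, fmr=0.005, design=[key], seed=101
    )
    return tables[key], truth


def make_table(records: list[tuple], key: SampleKey | None = None,
               spike: list[tuple] | None = None) -> SampleTable:
    """records: (chrom, pos, strand, context, n_total, n_meth) tuples."""
    cols = ["chrom", "pos", "strand", "context", "n_total", "n_meth"]
    df = pd.DataFrame(records, columns=cols)
    sp = pd.DataFrame(spike or [], columns=cols)
    return SampleTable(
        key=key or SampleKey("sim", "root", "control23", 1),
        records=df,
        spikein=sp,
    )
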