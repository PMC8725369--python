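"""Shared fixtures: a small seeded synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from regenmeth.meth_io import MethylCallTable
from regenmeth.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Toy study: 40 genes on 2 x 120 kb chromosomes, defaults otherwise."""
    return SimConfig(n_genes=40, chrom_length=120_000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def make_table():
    """Build a MethylCallTable from (chrom, pos, strand, context, tri, meth, unmeth) rows."""

    def _make(rows, sample_id="s1", condition=""):
        df = pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "context", "trinucleotide", "meth", "unmeth"],
        )
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        return MethylCallTable(sample_id, condition, df)

    return _make


@pytest.fixture
def null_region_counts():
    """Draw beta-binomial region-level counts with no group difference.

    Mirrors the study design: per region, per replicate coverage is Poisson
    around 3 sites x 15x, replicate proportions Beta-dispersed (phi = 0.01)
    around a region-specific baseline.
    """

    def _draw(m, rng, n_rep=3, coverage=45.0, phi=0.01, base=None):
        if base is None:
            base = rng.uniform(0.1, 0.85, size=m)
        total = rng.poisson(coverage, size=(m, n_rep))
        s = (1 - phi) / phi
        props = rng.beta(base[:, None] * s, (1 - base[:, None]) * s, size=(m, n_rep))
        meth = rng.binomial(total, props)
        return meth, total, base

    return _draw
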