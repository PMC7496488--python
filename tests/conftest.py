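"""Shared fixtures: small synthetic genomes and panels built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnvsd.intervals import IntervalSet
from cnvsd.simulate import (
    SimGenomeParams,
    SimPanelParams,
    simulate_genome,
    simulate_panel_counts,
)


@pytest.fixture(scope="session")
def small_genome():
    """2 x 500 kb genome with a handful of SDs and genes; quick to build."""
    return simulate_genome(
        SimGenomeParams(
            n_chroms=2,
            chrom_length=500_000,
            n_genes=80,
            n_sd_pairs=8,
            repeat_fraction=0.2,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_panel(small_genome):
    """40-sample panel with 40 planted CNV sites on the small genome."""
    return simulate_panel_counts(
        small_genome, SimPanelParams(n_samples=40, n_cnv_sites=40, seed=12)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_pos: int = 10_000,
    max_len: int = 500,
) -> IntervalSet:
    rows = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, max_pos))
        l = int(rng.integers(1, max_len + 1))
        rows.append((c, s, s + l))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
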