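"""Shared fixtures: cytosine-table builders and a default simulated dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylspread.simulate import SimulationConfig, simulate_dataset


def make_cytosines(rows) -> pd.DataFrame:
    """Build a cytosine table from (chrom, pos, strand, meth, unmeth, context)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "meth", "unmeth", "context"]
    )


def random_cytosines(rng: np.random.Generator, n: int, chrom_len: int = 10_000,
                     chroms=("Chr1",), contexts=("CG", "CHG", "CHH"),
                     max_depth: int = 20) -> pd.DataFrame:
    pos = rng.integers(1, chrom_len + 1, size=n)
    depth = rng.integers(0, max_depth + 1, size=n)
    meth = rng.binomial(depth, rng.uniform(0, 1, size=n))
    return make_cytosines(
        list(zip(
            rng.choice(list(chroms), size=n),
            pos,
            rng.choice(["+", "-"], size=n),
            meth,
            depth - meth,
            rng.choice(list(contexts), size=n),
        ))
    )


def random_intervals(rng: np.random.Generator, n: int, span: int = 5_000,
                     max_len: int = 120, chroms=("Chr1",)) -> pd.DataFrame:
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(list(chroms), size=n),
            "start": starts,
            "end": starts + lengths,
        }
    )


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_ds(default_config):
    """The default-conditions simulated dataset (shared; do not mutate)."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced genome for I/O-heavy tests (CLI, determinism)."""
    return SimulationConfig(
        seed=5, chrom_length=120_000, n_blocks_per_chrom=60,
        te_counts={"cCMT2": 10, "cRdDM": 16, "eRdDM": 14},
        n_independent_clusters_per_chrom=8,
    )
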