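import numpy as np
import pandas as pd
import pytest

from getmm import SimConfig, simulate_counts


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """8-gene x 3-sample matrix with a dominant gene in sample a.

    The same matrix was fed to edgeR / DESeq2 to freeze cross-package
    reference factors (see test_tmm.py).
    """
    return pd.DataFrame(
        [
            [1200, 300, 150],
            [50, 600, 40],
            [800, 850, 900],
            [0, 20, 10],
            [250, 260, 270],
            [90, 10, 400],
            [30, 35, 25],
            [5000, 400, 300],
        ],
        index=[f"g{i}" for i in range(1, 9)],
        columns=["a", "b", "c"],
        dtype=np.int64,
    )


@pytest.fixture
def small_lengths(small_counts) -> pd.Series:
    return pd.Series(
        [500, 1500, 2000, 800, 1200, 3000, 600, 10000],
        index=small_counts.index,
        name="length",
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The package's reference simulation scenario (seeded)."""
    cfg = SimConfig(seed=7)
    return cfg, simulate_counts(cfg)


@pytest.fixture
def panel_matrix() -> pd.DataFrame:
    genes = ["BGN", "FAP", "INHBA", "MKI67", "MYC", "MYBL2", "GADD45B"]
    rng = np.random.default_rng(11)
    return pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(7, 3)), index=genes, columns=["s1", "s2", "s3"]
    )
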