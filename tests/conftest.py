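"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from degrepro import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """200-gene dataset over 12+12 samples: enough for n = 3 with four repeats."""
    cfg = SimConfig(
        n_genes=200, n_tumor_pool=12, n_normal_pool=12, seed=42, outlier_rate=0.0
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def hetero_sim():
    """Default heterogeneous study profile (2000 genes, 60+60 pools, outliers)."""
    return simulate_dataset(SimConfig(seed=3))


@pytest.fixture()
def toy_counts():
    """Deterministic 6-gene, 4-sample integer matrix with hand-checkable structure."""
    rng = np.random.default_rng(7)
    arr = rng.integers(5, 500, size=(6, 4))
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(6)],
        columns=["T1", "T2", "N1", "N2"],
    )


@pytest.fixture()
def toy_annotation():
    return pd.Series(
        {"T1": "tumor", "T2": "tumor", "N1": "normal", "N2": "normal"}, name="group"
    )
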