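"""Shared fixtures: small simulated landscapes reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from landgen.synthetic import SimConfig, patchy_habitat, simulate_dataset


@pytest.fixture(scope="session")
def ds_small():
    """Smooth-landscape dataset: 24 locations x 10 diploids, 292 SNPs
    (12 planted clines), neutral covariance driven by habitat resistance."""
    cfg = SimConfig(shape=(40, 40), n_populations=24, n_individuals=10,
                    n_neutral=280, n_adaptive=12, seed=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def ds_patchy():
    """Four habitat blocks separated by near-impassable barriers: strong,
    well-separated population structure for clustering and zone tests."""
    cfg = SimConfig(shape=(40, 40), n_populations=24, n_individuals=10,
                    n_neutral=280, n_adaptive=12, phi=30.0, seed=11)
    hab = patchy_habitat((40, 40), blocks=(2, 2), barrier_width=3,
                         high=0.9, low=0.02)
    return simulate_dataset(cfg, habitat=hab)


@pytest.fixture(scope="session")
def env_toy():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.standard_normal((40, 5)),
                        columns=[f"v{i}" for i in range(5)])
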