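import numpy as np
import pytest

from fishflow import simkit


@pytest.fixture(scope="session")
def small_experiment():
    """A rendered 4-round, 2-gene experiment shared across tests."""
    cfg = simkit.SimConfig(
        n_rounds=4,
        n_cells=6,
        field_shape=(9, 256, 256),
        seed=42,
        genes={"XPO1": {"hela": 15.0}, "KIF1C": {"hela": 15.0}},
        drift_per_round_px=4.0,
    )
    stacks, truth = simkit.generate_experiment(cfg)
    return cfg, stacks, truth


@pytest.fixture(scope="session")
def single_gene_truth():
    """Ground-truth-only 20-round single-gene experiment (no images)."""
    cfg = simkit.SimConfig(
        n_rounds=20,
        n_cells=30,
        field_shape=(9, 512, 512),
        seed=7,
        nucleus_radius_px=14,
        genes={"XPO1": {"hela": 15.0}},
        round_plan=tuple(("XPO1", False) for _ in range(20)),
        redetect_prob=0.9,
        localization_jitter_px=0.1,
        drift_per_round_px=5.0,
    )
    _, truth = simkit.generate_experiment(cfg, render=False)
    return cfg, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
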