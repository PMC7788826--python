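"""Shared fixtures: scaled-down synthetic datasets reused across test modules."""

import numpy as np
import pytest

from pmdecon import SimulationConfig, simulate_cell_profiles


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 6 cell types, both trimesters, 4000 probes."""
    return SimulationConfig(
        n_probes=4000,
        n_replicates_per_type=6,
        n_hypo_dmcs_per_type=120,
        n_hyper_dmcs_per_type=80,
        n_pmd_blocks=8,
        pmd_block_size=25,
        n_imprint_probes=60,
        n_repeat_probes=200,
        n_gestational_dmcs_per_type=40,
        n_villi_per_trimester=3,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_cell_profiles(small_config)


@pytest.fixture(scope="session")
def term_reference(small_dataset):
    from pmdecon import build_reference

    return build_reference(small_dataset.beta, small_dataset.samples, trimester="term")


@pytest.fixture(scope="session")
def default_dataset():
    """Full default study conditions (20k probes, 6 cell types, 2 trimesters)."""
    return simulate_cell_profiles(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_term_reference(default_dataset):
    from pmdecon import build_reference

    return build_reference(default_dataset.beta, default_dataset.samples, trimester="term")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
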