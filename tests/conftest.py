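"""Shared fixtures.

The heavy session-scoped fixtures simulate the study protocols once and
are shared by the acceptance tests: a 10-network fiducial ensemble
(120 s sleep each, headline-trajectory decoding), a 5-network
two-environment ensemble with all four trajectory decodings, and a
reduced (n_clusters, participation, p_ee) sweep for the small-world
analyses.
"""

from __future__ import annotations

import numpy as np
import pytest

from clusterplay.config import RunConfig, with_overrides
from clusterplay.experiment import run_fiducial, run_grid, run_multi_environment
from clusterplay.netgen import build_network


@pytest.fixture(scope="session")
def fiducial_config() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def fiducial_network(fiducial_config):
    """One fiducial network realization (no simulation)."""
    return build_network(fiducial_config, seed=11)


@pytest.fixture(scope="session")
def fiducial_ensemble(fiducial_config):
    """Ten fiducial networks with 120 s sleep and headline decoding."""
    return run_fiducial(
        fiducial_config, n_networks=10, directions=("left",), compute_graph=True
    )


@pytest.fixture(scope="session")
def multi_env_result():
    """Five networks, two environments, all four trajectory decodings."""
    return run_multi_environment(RunConfig(seed=3), n_networks=5, n_environments=2)


@pytest.fixture(scope="session")
def swi_sweep():
    """Reduced parameter sweep at three E-E connection probabilities."""
    return run_grid(
        RunConfig(seed=5),
        n_clusters_values=(10, 20),
        participation_values=(1.25, 1.75),
        p_ee_values=(0.04, 0.08, 0.12),
        n_networks=4,
        sleep_duration=120.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
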