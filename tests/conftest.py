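import numpy as np
import pytest

from transcpm import CohortConfig, generate_cohort

SMALL_GROUPS = {"HC": 24, "SCZ": 12, "BPAD": 12, "ADHD": 12}


@pytest.fixture(scope="session")
def small_cohort():
    """Signal-bearing desk-scale cohort: 60 subjects, 30 nodes, 2 tasks."""
    cfg = CohortConfig(
        group_sizes=dict(SMALL_GROUPS), n_nodes=30, n_tasks=2,
        n_signal_edges=25, n_group_edges=10, seed=11,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Same shape, nothing planted: no trait effect, no group shifts."""
    cfg = CohortConfig(
        group_sizes=dict(SMALL_GROUPS), n_nodes=30, n_tasks=2,
        n_signal_edges=0, n_group_edges=0, effect_size=0.0, seed=12,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
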