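import dataclasses

import numpy as np
import pytest

from efcpipe import CVConfig, SimParams, default_planted_edges, generate_cohort


def tiny_sim_params(seed: int = 0, delta: float = 0.4, **kwargs) -> SimParams:
    """A fast 16-ROI, 8+8-subject cohort for protocol-level tests."""
    defaults = dict(
        n_group_a=8,
        n_group_b=8,
        T=120,
        R=16,
        M=4,
        planted_edges=default_planted_edges(16, 4, n_edges=8),
        delta=delta,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimParams(**defaults)


def tiny_cv_config(seed: int = 0, **kwargs) -> CVConfig:
    defaults = dict(
        outer_folds=4,
        inner_folds=3,
        repetitions=2,
        window_grid=(20,),
        cluster_grid=(8,),
        seed=seed,
    )
    defaults.update(kwargs)
    return CVConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    cohort, truth = generate_cohort(tiny_sim_params(seed=3))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
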