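import numpy as np
import pytest

from leviathan import GroupAssignment, ModelParams


@pytest.fixture
def small_params() -> ModelParams:
    """6-agent two-group parameter set for fast micro-dynamics tests."""
    return ModelParams(
        n_agents=6,
        n_small=3,
        n_large=3,
        sigma_small=0.1,
        sigma_large=0.15,
        noise_half_width=0.2,
        gossip_count=3,
        n_iterations=100,
        measure_every=10,
        seed=7,
    )


@pytest.fixture
def small_groups(small_params) -> GroupAssignment:
    return GroupAssignment.from_params(small_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def constant_column_matrix(reputations, self_esteem=0.0):
    """Esteem matrix whose off-diagonal column j is constant, so that
    reputation[j] equals exactly the requested value."""
    n = len(reputations)
    a = np.tile(np.asarray(reputations, dtype=float), (n, 1))
    np.fill_diagonal(a, self_esteem)
    return a
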