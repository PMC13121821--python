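import numpy as np
import pytest

from irtstream.model import (
    ItemParamSet,
    ItemParamVector,
    ResponseVector,
    build_quadrature_grid,
)


@pytest.fixture
def two_node_grid():
    """K=2, Q=1 Gauss-Hermite grid: nodes (-1, +1), weights (1/2, 1/2)."""
    return build_quadrature_grid(2, 1)


@pytest.fixture
def unit_item():
    """Single 2PL item with discrimination 1 and intercept 0."""
    return ItemParamVector(np.array([1.0]), 0.0)


@pytest.fixture
def unit_item_set(unit_item):
    return ItemParamSet([unit_item])


@pytest.fixture
def correct_response():
    return ResponseVector([1], examinee_id="e1")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, J=None, Q=None, K=5):
    """Small random item set + response vector + grid for oracle checks."""
    J = J if J is not None else int(rng.integers(2, 6))
    Q = Q if Q is not None else int(rng.integers(1, 3))
    grid = build_quadrature_grid(K, Q)
    beta = np.hstack([rng.uniform(0.5, 2.0, (J, Q)), rng.standard_normal((J, 1))])
    params = ItemParamSet.from_arrays(beta)
    y = ResponseVector(rng.integers(0, 2, J))
    return params, y, grid
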