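import numpy as np
import pytest

from advbpr.core import FactorModel, Hyperparams
from advbpr.data import (
    InteractionMatrix,
    ProfileMatrix,
    TripleSet,
    build_interaction_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_profiles(rng):
    """Two drugs, three targets, 6-dimensional profiles."""
    drugs = ProfileMatrix(
        entity_ids=["d1", "d2"], features=rng.standard_normal((2, 6))
    )
    targets = ProfileMatrix(
        entity_ids=["t1", "t2", "t3"], features=rng.standard_normal((3, 6))
    )
    return drugs, targets


@pytest.fixture
def tiny_im(tiny_profiles):
    drugs, targets = tiny_profiles
    return build_interaction_matrix(drugs, targets, [("d1", "t1"), ("d2", "t2")])


@pytest.fixture
def small_model(rng):
    """Random factor model: 6 drugs, 10 targets, latent dimension 4."""
    return FactorModel(
        F_D=rng.standard_normal((6, 4)), F_T=rng.standard_normal((10, 4))
    )


@pytest.fixture
def small_triples(rng):
    """Valid-shaped random triples over the small_model index space."""
    rows = []
    for i in range(6):
        for _ in range(3):
            j = int(rng.integers(0, 5))
            k = int(5 + rng.integers(0, 5))
            rows.append((i, j, k))
    return TripleSet(np.asarray(rows))


@pytest.fixture
def default_hp():
    return Hyperparams(f=4, seed=0, n_epochs=5)
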