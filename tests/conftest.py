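import numpy as np
import pytest

from multiarrange import (
    SubjectModel,
    make_toy_tetrahedron,
    simulate_arrangement,
)


@pytest.fixture(scope="session")
def toy_truth():
    return make_toy_tetrahedron()


@pytest.fixture(scope="session")
def toy_trials(toy_truth):
    """The two-arrangement toy log: full set plus the first three items."""
    model = SubjectModel(truth=toy_truth, noise_sd=0.0, seed=0)
    arr1 = simulate_arrangement(model, list(toy_truth.items), 1)
    arr2 = simulate_arrangement(model, list(toy_truth.items)[:3], 2)
    return [arr1, arr2]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
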