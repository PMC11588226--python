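import numpy as np
import pytest

from faaknn.basis import FunctionalSample, make_discrete_basis


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def planar_eight(rng):
    """Eight seeded points in the plane, the classic tiny AA benchmark."""
    return rng.normal(size=(8, 2)) * np.array([2.0, 1.0]) + np.array([1.0, -0.5])


@pytest.fixture()
def three_cluster_curves():
    """Thirty curves in three tight, well-separated groups on a grid."""
    grid = np.linspace(0.0, 1.0, 25)
    gen = np.random.default_rng(7)
    means = [2.0 * grid, 2.0 * (1.0 - grid), np.full(25, 3.0)]
    rows = [mu + 0.05 * gen.standard_normal((10, 25)) for mu in means]
    basis = make_discrete_basis(25, 0.0, 1.0)
    return FunctionalSample(np.vstack(rows), basis, grid=grid)
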