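import numpy as np
import pytest

import clustvar as cv


def make_stationary_model(M: int, rng: np.random.Generator,
                          radius: float = 0.6) -> cv.VARModel:
    """A random VAR(1) model rescaled to a given spectral radius."""
    phi = rng.uniform(-0.5, 0.5, size=(M, M))
    phi *= radius / np.max(np.abs(np.linalg.eigvals(phi)))
    c = rng.uniform(-1, 1, size=M)
    return cv.VARModel(c, phi, np.eye(M), n_pairs=0, sse=0.0)


def simulate_series(model: cv.VARModel, T: int,
                    rng: np.random.Generator, noise: float = 1.0) -> np.ndarray:
    """One series driven by iid normal innovations (noise=0 -> exact)."""
    M = model.n_variables
    y = np.empty((T, M))
    y[0] = rng.standard_normal(M) if noise else np.ones(M)
    for t in range(1, T):
        u = noise * rng.standard_normal(M) if noise else 0.0
        y[t] = model.intercept + model.slopes @ y[t - 1] + u
    return y


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_panel(rng):
    """Three persons, two variables, mixed segment structure."""
    return cv.panel_from_arrays({
        "a": rng.standard_normal((12, 2)),
        "b": [rng.standard_normal((6, 2)), rng.standard_normal((5, 2))],
        "c": rng.standard_normal((8, 2)),
    }, variable_names=("x", "y"))


@pytest.fixture
def two_cluster_dataset():
    """An easy, well-separated two-cluster instance (long series)."""
    cell = cv.DesignCell(2, 500, 30, "highly_dissimilar", "equal", "equal")
    return cv.generate_dataset(cell, 0, seed=31)
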