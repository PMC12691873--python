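import numpy as np
import pytest

from mesfsurv import build_adjacency, make_lattice


@pytest.fixture(scope="session")
def rook44():
    return make_lattice(4, 4, rule="rook")


@pytest.fixture(scope="session")
def rook1010():
    return make_lattice(10, 10, rule="rook")


@pytest.fixture(scope="session")
def path3():
    return build_adjacency(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def simple_sim():
    """Small spatially structured simulation shared across model tests."""
    from mesfsurv import simulate_dataset

    dataset, graph, truth, specs = simulate_dataset(
        rows=8, cols=8, n_per_region=60, covariate_model="simple",
        spatial_indices=[0, 1], spatial_sd=0.3, noise_sd=0.1, seed=42,
    )
    return dataset, graph, truth, specs


def moran_oracle(values: np.ndarray, C: np.ndarray) -> float:
    """Direct double-loop Moran's I, independent of the package routines."""
    z = values - values.mean()
    n = len(z)
    s0 = C.sum()
    num = sum(
        C[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return (n / s0) * num / (z @ z)
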