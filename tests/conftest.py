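import numpy as np
import pandas as pd
import pytest

from knotpop import BandMatrix, default_config, simulate_band_matrix


@pytest.fixture
def tiny_bm() -> BandMatrix:
    """4 samples x 5 bands over two primers, two populations, no missing."""
    values = pd.DataFrame(
        [[1, 0, 1, 1, 0],
         [1, 0, 1, 0, 0],
         [0, 1, 0, 1, 1],
         [0, 1, 1, 1, 1]],
        index=["a1", "a2", "b1", "b2"],
        columns=["P1::x1", "P1::x2", "P1::x3", "P2::y1", "P2::y2"],
        dtype=float)
    pops = pd.Series(["A", "A", "B", "B"], index=values.index)
    return BandMatrix(values, pops)


@pytest.fixture(scope="session")
def preset():
    """Desk-scale synthetic preset mirroring the 5+7+3 study design."""
    return default_config(seed=11)


@pytest.fixture(scope="session")
def preset_bm(preset):
    bm, truth = simulate_band_matrix(preset)
    return bm, truth


def random_band_matrix(rng: np.random.Generator, n: int, L: int,
                       n_pops: int = 2) -> BandMatrix:
    """Exchangeable Bernoulli(0.5) matrix with round-robin labels."""
    values = pd.DataFrame(
        rng.integers(0, 2, size=(n, L)).astype(float),
        index=[f"s{i}" for i in range(n)],
        columns=[f"P1::b{j}" for j in range(L)])
    pops = pd.Series([f"pop{i % n_pops}" for i in range(n)],
                     index=values.index)
    return BandMatrix(values, pops)
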