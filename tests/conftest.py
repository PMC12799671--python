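import numpy as np
import pytest

from fabricopt import (
    ElasticConstants,
    FabricTensor,
    SetPoints,
    StressState,
    YieldConstants,
    default_elastic,
    default_yield,
)


@pytest.fixture(scope="session")
def elastic() -> ElasticConstants:
    """Representative trabecular-bone elastic constants (10 GPa, nu 0.25, k=2)."""
    return default_elastic()


@pytest.fixture(scope="session")
def yield_constants() -> YieldConstants:
    """Compact quadric yield constants (54/72 MPa, zeta 0.3, p=2)."""
    return default_yield()


@pytest.fixture(scope="session")
def set_points() -> SetPoints:
    return SetPoints()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_fabric(rng: np.random.Generator, d: int = 3) -> FabricTensor:
    ratios = np.sort(rng.uniform(0.3, 1.0, d - 1))
    m = np.concatenate([ratios, [1.0]])
    return FabricTensor.from_eigenvalues(m, normalise=True)


def random_direction(rng: np.random.Generator, d: int = 3,
                     signs: np.ndarray | None = None) -> StressState:
    mags = rng.uniform(0.2, 1.0, d)
    if signs is None:
        signs = rng.choice([-1.0, 1.0], d)
    sigma = mags * np.asarray(signs, dtype=float)
    return StressState.from_principal(d * sigma / np.abs(sigma).sum())
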