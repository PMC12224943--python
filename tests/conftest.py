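import numpy as np
import pytest

from synspread import (
    Connectome,
    FitConfig,
    RegionAtlas,
    SeedSpec,
    SpreadParameters,
    SyntheticConfig,
    synth_bundle,
)


@pytest.fixture
def atlas_ab():
    return RegionAtlas(("A", "B"))


@pytest.fixture
def conn_ab(atlas_ab):
    """Single directed edge A -> B with weight 1."""
    return Connectome(atlas_ab, np.array([[0.0, 1.0], [0.0, 0.0]]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connectome(rng, n=10, density=0.4):
    w = np.where(rng.random((n, n)) < density, rng.lognormal(0.0, 1.0, (n, n)), 0.0)
    np.fill_diagonal(w, 0.0)
    w /= max(w.sum(axis=0).max(), 1.0)
    return Connectome(RegionAtlas(tuple(f"R{i}" for i in range(n))), w)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """20-region noiseless study for fast exact-recovery checks."""
    cfg = SyntheticConfig(
        n_regions=20, noise_sigma=0.0, detection_floor=0.0, n_genes=0, rng_seed=42
    )
    return synth_bundle(cfg)


@pytest.fixture
def fast_fit_config():
    return FitConfig(n_starts=4, rng_seed=7)
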