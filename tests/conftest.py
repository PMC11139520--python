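import numpy as np
import pytest

from cellasr.atlas import AtlasConfig, build_atlas
from cellasr.synthetic import (
    PhantomConfig,
    WormConfig,
    make_phantom,
    make_synthetic_atlas,
    make_synthetic_worm,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A 16x32x32 phantom with a handful of separated cells."""
    return make_phantom(
        PhantomConfig(shape=(16, 32, 32), n_cells=4, min_separation=10.0, seed=7)
    )


@pytest.fixture(scope="session")
def worm_cfg():
    return WormConfig(n_cells=60, tube_length=300.0, n_samples=12, seed=5)


@pytest.fixture(scope="session")
def worm_template(worm_cfg):
    return make_synthetic_atlas(worm_cfg)


@pytest.fixture(scope="session")
def worm_atlas(worm_cfg, worm_template):
    samples = [
        make_synthetic_worm(worm_template, worm_cfg, seed=900 + s)
        for s in range(worm_cfg.n_samples)
    ]
    return build_atlas(samples, AtlasConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
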