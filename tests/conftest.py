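import numpy as np
import pytest

from crownseg import (
    HeightGrids,
    RuleConfig,
    SceneRaster,
    SceneSpec,
    Transform,
    generate_scene,
)


@pytest.fixture
def tf():
    return Transform(origin_x=0.0, origin_y=10.0, pixel_size=0.1)


@pytest.fixture
def cfg():
    return RuleConfig()


def flat_scene(value: float, shape=(40, 40), tf=None) -> SceneRaster:
    tf = tf or Transform(0.0, shape[0] * 0.1, 0.1)
    g = np.full(shape, float(value))
    return SceneRaster(g.copy(), g.copy(), g.copy(), tf)


def flat_heights(shape=(40, 40), tf=None) -> HeightGrids:
    tf = tf or Transform(0.0, shape[0] * 0.1, 0.1)
    return HeightGrids(dem=np.zeros(shape), dsm=np.zeros(shape), transform=tf)


@pytest.fixture(scope="session")
def small_spec():
    """A compact scene that exercises every class yet runs in seconds."""
    return SceneSpec(
        rng_seed=7,
        noise_sd=0.0,
        height_noise_sd=0.0,
        extent_m=(50.0, 50.0),
        n_sapote=5,
        n_algarrobo_alive=5,
        n_algarrobo_dead=1,
        dead_cluster_size=0,
        n_overo=2,
        border_margin_m=8.0,
        plot_margin_m=2.0,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)
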