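import numpy as np
import pytest

from urbanhealth.geo import GeoRaster, WorldTransform
from urbanhealth.synthetic import SyntheticCityConfig, generate_city

TEST_TILE = 32  # small tiles keep the suite fast; geometry is size-agnostic


@pytest.fixture(scope="session")
def small_city():
    """A 20 x 20-tile synthetic city with the four default archetypes."""
    config = SyntheticCityConfig(
        raster_rows=TEST_TILE * 20,
        raster_cols=TEST_TILE * 20,
        tile_size=TEST_TILE,
        n_tracts=60,
        seed=1,
    )
    return generate_city(config)


@pytest.fixture()
def unit_transform():
    """1 m/pixel north-up transform with origin at the map origin."""
    return WorldTransform(pixel_size_x=1.0, pixel_size_y=-1.0, origin_x=0.5, origin_y=-0.5)


@pytest.fixture()
def gradient_raster(unit_transform):
    """64 x 64 raster whose red channel encodes the column index."""
    rows = cols = 64
    px = np.zeros((rows, cols, 3), dtype=np.uint8)
    px[..., 0] = (np.arange(cols) * 255 // (cols - 1)).astype(np.uint8)
    return GeoRaster(pixels=px, transform=unit_transform)


def multinomial_sample(x: np.ndarray, betas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw labels 1..K from a multinomial logit with baseline cluster 1.

    ``x`` is (n, p); ``betas`` is (K-1, p+1) rows = contrasts 2..K,
    columns = intercept then slopes.
    """
    n = x.shape[0]
    design = np.hstack([np.ones((n, 1)), x])
    eta = design @ betas.T  # (n, K-1)
    logits = np.hstack([np.zeros((n, 1)), eta])
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1) + 1
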