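import numpy as np
import pytest

from cloudspectra.cloud import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """100 random points with unit normals and colors."""
    n = 100
    normals = rng.normal(size=(n, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(
        positions=rng.uniform(-5, 5, size=(n, 3)),
        normals=normals,
        colors=rng.uniform(0, 1, size=(n, 3)),
        attributes={"ndvi": rng.uniform(-1, 1, size=n)},
    )
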