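import numpy as np
import pytest

from adrenomics.texture import QuantizedVOI, quantize
from adrenomics.volume import VOISample


def make_sample(values, coords=None, shape=None):
    """Build a VOISample from explicit values (and coords on a grid)."""
    values = np.asarray(values, dtype=float)
    if coords is None:
        if shape is None:
            shape = (values.size, 1, 1)
        coords = np.argwhere(np.ones(shape, dtype=bool))[: values.size]
    return VOISample(values=values, coords=np.asarray(coords))


def random_voi(rng: np.random.Generator, max_dim: int = 6, ng: int = 8):
    """A random small VOI on a random grid: (quantized VOI, grid shape).

    The mask is random with holes, so chains break and boundary handling is
    exercised; at least two voxels are guaranteed.
    """
    shape = tuple(int(rng.integers(2, max_dim + 1)) for _ in range(3))
    mask = rng.random(shape) < rng.uniform(0.3, 0.9)
    while mask.sum() < 2:
        mask |= rng.random(shape) < 0.5
    values = rng.integers(0, 50, size=shape).astype(float)
    coords = np.argwhere(mask)
    sample = VOISample(values=values[mask], coords=coords)
    ng_eff = int(rng.integers(2, ng + 1))
    return quantize(sample, ng_eff), shape


def level_grid_of(q: QuantizedVOI, shape) -> np.ndarray:
    grid = np.zeros(shape, dtype=np.int64)
    grid[tuple(q.coords.T)] = q.levels
    return grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
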