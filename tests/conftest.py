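import numpy as np
import pytest

from dabquant import StainModel, SyntheticSpec, generate_tile


@pytest.fixture(scope="session")
def model() -> StainModel:
    return StainModel()


@pytest.fixture(scope="session")
def balanced_tile():
    """One 256x256 tile with 5 nuclei per class, no overlap, seed fixed."""
    return generate_tile(SyntheticSpec(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_instance_mask(rng: np.random.Generator, shape=(64, 64), n_blobs=8) -> np.ndarray:
    """Random label raster of rectangular blobs (may touch or nest holes)."""
    labels = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_blobs + 1):
        h = int(rng.integers(2, 12))
        w = int(rng.integers(2, 12))
        r = int(rng.integers(0, shape[0] - h))
        c = int(rng.integers(0, shape[1] - w))
        labels[r : r + h, c : c + w] = k
    return labels
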