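import numpy as np
import pytest

from vasarad.types import MaskedVolume


def random_masked_volume(rng, shape=(6, 6, 6), mask_p=0.7, n_levels=4):
    """Small random volume whose in-mask intensities hit integer levels."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[tuple(d // 2 for d in shape)] = True
    intensities = rng.integers(0, n_levels, size=shape).astype(float)
    # ensure full level range so discretization maps value k -> level k+1
    flat = np.flatnonzero(mask)
    intensities.ravel()[flat[0]] = 0
    if flat.size > 1:
        intensities.ravel()[flat[1]] = n_levels - 1
    return MaskedVolume(intensities, mask, (1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volumes(rng):
    """A batch of random 6x6x6 masked volumes for oracle comparisons."""
    return [random_masked_volume(rng) for _ in range(20)]
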