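import numpy as np
import pytest

from radstab import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_spec():
    """A small, fast phantom spec with fixed acquisition (no gain/offset)."""
    return PhantomSpec(n_subjects=4, shape=(8, 26, 26), spacing=(1.0, 1.0, 3.0),
                       gain_sd=0.0, offset_sd=0.0, lesion_center_jitter_mm=0.0,
                       lesion_radius_sd_mm=0.5, seed=11)


def random_level_grid(rng, max_side=6, ng=4, p_roi=0.8):
    """Random small level grid with 0 = outside ROI, levels 1..ng inside."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    grid = rng.integers(1, ng + 1, size=shape)
    grid[rng.random(shape) > p_roi] = 0
    if not (grid > 0).any():
        grid[0, 0, 0] = 1
    return grid
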