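import numpy as np
import pytest

from bogmap import synthetic as syn

#: Class shares used across the suite (mirrors a realistic raised-bog mix:
#: grassland-dominated with ~1% water and built-up).
PROPORTIONS = (0.10, 0.11, 0.43, 0.21, 0.13, 0.01, 0.01)


@pytest.fixture(scope="session")
def signatures():
    return syn.default_signatures()


@pytest.fixture(scope="session")
def truth_map():
    """150x150 contiguous-patch truth map with all seven classes."""
    return syn.generate_class_map(150, 150, PROPORTIONS, patch_scale=15, seed=1)


@pytest.fixture(scope="session")
def scene_series(truth_map, signatures):
    """Ten noisy scenes with 5-40% blob clouds over the shared truth map."""
    return syn.generate_scene_series(
        truth_map, signatures, 10, (0.05, 0.4), seed=3
    )


@pytest.fixture(scope="session")
def clean_scene(truth_map, signatures):
    """Single noiseless, cloud-free scene: bands equal the class means."""
    return syn.generate_scene_series(
        truth_map, signatures, 1, (0.0, 0.0), seed=5, noise_sd=0.0
    )[0]


def degrade_map(truth, flip_rate, seed):
    """Imperfect classifier stand-in: flip a fraction of pixels at random."""
    rng = np.random.default_rng(seed)
    flip = rng.random(truth.shape) < flip_rate
    other = rng.integers(1, 8, size=truth.shape)
    return syn.ClassMap(
        np.where(flip, other, truth.grid).astype(np.int16),
        pixel_size_ha=truth.pixel_size_ha,
    )
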