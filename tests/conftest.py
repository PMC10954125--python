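import numpy as np
import pytest

from dermpipe.synthgen import LesionSpec, add_speckle


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_region_speckled():
    """Piecewise-constant two-region image plus multiplicative speckle.

    Returns (clean, noisy): left half 80, right half 180, speckle
    variance 0.05 with a fixed seed.
    """
    clean = np.full((128, 128), 80.0)
    clean[:, 64:] = 180.0
    noisy = add_speckle(clean, variance=0.05, seed=777)
    return clean, noisy


@pytest.fixture()
def clean_lesion_spec():
    """Hair-free, well-contrasted lesion spec with ground-truth mask."""
    return LesionSpec(
        class_id="MEL",
        image_size=(128, 128),
        ellipse_center=(60.0, 70.0),
        axes=(32.0, 24.0),
        rotation=0.6,
        lesion_intensity_mean=80.0,
        background_mean=200.0,
        border_irregularity=0.12,
        hair_count=0,
        speckle_var=0.05,
        seed=42,
    )
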