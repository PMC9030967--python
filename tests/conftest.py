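import numpy as np
import pytest

from eotrh_texture.texture_engine import QuantizedPatch


def random_masked_patch(rng: np.random.Generator, size=None, n_levels=None):
    """A random intensity patch with an irregular mask of >= 16 pixels."""
    if size is None:
        size = int(rng.integers(12, 17))
    shape = (size, size)
    patch = rng.uniform(0.0, 255.0, shape)
    field = rng.normal(size=shape)
    # smooth threshold field -> blobby mask; keep enough foreground
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(field, 2.0)
    mask = smooth > np.quantile(smooth, 0.4)
    if mask.sum() < 16:
        mask = np.ones(shape, dtype=bool)
    return patch, mask


def random_quantized_patch(rng: np.random.Generator, size=None, n_g=None):
    """A random QuantizedPatch with few levels (interesting runs/zones)."""
    if size is None:
        size = int(rng.integers(12, 17))
    if n_g is None:
        n_g = int(rng.integers(2, 7))
    patch, mask = random_masked_patch(rng, size=size)
    levels = np.zeros((size, size), dtype=np.int64)
    levels[mask] = rng.integers(1, n_g + 1, size=int(mask.sum()))
    n_g_actual = int(levels.max())
    return QuantizedPatch(levels=levels, n_g=n_g_actual, bin_width=1.0, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 teeth, 3 per grade — shared by fast structural tests."""
    from eotrh_texture.synthetic_cohort import CohortConfig, generate_cohort

    config = CohortConfig(
        n_subjects=2,
        teeth_per_subject=6,
        grade_counts=(3, 3, 3, 3),
        n_excluded=0,
        rng_seed=12345,
    )
    teeth, grades = generate_cohort(config)
    return config, teeth, grades
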