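import warnings

import numpy as np
import pytest

from tilepurify.synthetic import (
    DEFAULT_SPECS,
    SyntheticCohortConfig,
    cohort_to_dataset,
    generate_cohort,
    render_tile,
)


@pytest.fixture(autouse=True)
def _quiet_subset_fallback():
    # small test cohorts legitimately trigger the k-reduction fallback
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than 2k images")
        warnings.filterwarnings("ignore", message="class .* has only")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-class contaminated cohort small enough for per-test use."""
    config = SyntheticCohortConfig(
        n_images_per_class=6, image_size=128, tile_size=32, seed=11
    )
    images, truth = generate_cohort(config)
    return config, images, truth


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    config, images, truth = small_cohort
    return cohort_to_dataset(images, truth, config.tile_size)


@pytest.fixture(scope="session")
def class_tiles():
    """40 rendered tiles per class at 32 px, keyed by class name."""
    return {
        cls: [render_tile(spec, 9000 + i, size=32) for i in range(40)]
        for cls, spec in DEFAULT_SPECS.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
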