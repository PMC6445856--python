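import numpy as np
import pytest

import slidesample as ss


@pytest.fixture(scope="session")
def small_config() -> ss.CohortConfig:
    """A small, fast cohort configuration for structural tests."""
    return ss.CohortConfig(
        n_slides=6, grid_shape=(10, 10), target_foreground_tiles=60
    )


@pytest.fixture(scope="session")
def small_slide(small_config) -> ss.SyntheticSlide:
    return ss.generate_slide(small_config, slide_index=0, seed=11)


@pytest.fixture(scope="session")
def default_slide() -> ss.SyntheticSlide:
    """One slide at the study's scale (~900 foreground tiles)."""
    return ss.generate_slide(ss.CohortConfig(), slide_index=0, seed=17)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
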