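import numpy as np
import pytest

from facecue import GeneratorConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study used by several suites."""
    cfg = GeneratorConfig(
        seed=11,
        n_landmarks=40,
        n_ref_female=12,
        n_ref_male=14,
        n_participants=60,
        n_fathers=36,
        n_raters=120,
        ratings_per_face_per_trait=12,
        exclusion_counts={"no_photo": 4, "seriousness": 3, "language": 1, "duplicate": 1},
    )
    return simulate_study(cfg)
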