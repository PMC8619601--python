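import numpy as np
import pytest

from wavemri import PhantomParams


@pytest.fixture
def rng():
    return np.random.default_rng(20250917)


@pytest.fixture
def small_params():
    """Cheap 64x64 phantoms for unit tests (level-3 approx is 8x8)."""
    return PhantomParams(
        size=64,
        tissue_smoothness=2.0,
        lesion_radius=6.0,
        lesion_contrast=80.0,
        noise_density=0.02,
        seed=7,
    )
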