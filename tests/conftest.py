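import numpy as np
import pytest

from marc.core import AcquisitionGeometry
from marc.phantoms import Lesion, PhantomConfig, generate_phantom


@pytest.fixture
def small_geometry():
    """64x64 geometry with linear ordering, for formula-level tests."""
    return AcquisitionGeometry(matrix_rows=64, matrix_cols=64, ordering="linear")


@pytest.fixture
def phantom128():
    """A small textured phantom stack (128x128x7)."""
    return generate_phantom(PhantomConfig(matrix_rows=128, matrix_cols=128, seed=11))


@pytest.fixture
def lesion_config():
    """Phantom with a flat background and a lesion enhancing from phase 1 on."""
    return PhantomConfig(
        matrix_rows=128,
        matrix_cols=128,
        n_ellipses=6,
        phase_variation=0.0,
        lesion=Lesion(center=(64, 64), radius=9, enhancement_curve=[0, 1, 1, 1, 1, 1, 1]),
        seed=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
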