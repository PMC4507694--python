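import numpy as np
import pytest
from hypothesis import settings

from stripquant import KineticParams, SimulationConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture
def noise_free_cfg():
    """One spot per dilution level, zero noise — manifest equals output."""
    return SimulationConfig(
        replicates=1, pixel_noise_sd=0.0, replicate_noise_sd=0.0, seed=7
    )


def uniform_image(w=32, h=24, color=(100, 150, 200)):
    from stripquant import RGBImage

    px = np.empty((h, w, 3), dtype=np.uint8)
    px[:] = color
    return RGBImage(px)
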