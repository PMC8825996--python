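import numpy as np
import pytest

from neuroseason import synthgen


@pytest.fixture(scope="session")
def lamina_presets():
    return synthgen.cohort_presets("lamina")


@pytest.fixture(scope="session")
def small_spec():
    """A cheap cohort spec used where image content does not matter."""
    return synthgen.CohortSpec(
        label="A", mean_intensity=100.0, texture_density=0.5,
        texture_scale=1.5, noise_sd=10.0,
    )


@pytest.fixture()
def toy_image():
    """A 10x12 image with a plain full-frame mask."""
    rng = np.random.default_rng(0)
    pixels = rng.integers(0, 256, size=(10, 12)).astype(np.float32)
    return synthgen.NeuropilImage(
        pixels=pixels,
        mask=np.ones((10, 12), dtype=bool),
        animal_id="t001",
        cohort="A",
        kind="lamina",
    )
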