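import numpy as np
import pytest

from canopyphene import synthgen


@pytest.fixture(scope="session")
def wavelengths():
    return synthgen.default_wavelengths(204)


@pytest.fixture()
def scene():
    return synthgen.make_scene_truth((48, 48))


@pytest.fixture()
def noiseless_reflectance(scene, wavelengths):
    from canopyphene import hyperspec

    raw, white, dark, _ = synthgen.generate_hyperspectral_scene(
        scene, wavelengths, noise_sd=0.0
    )
    return hyperspec.calibrate(raw, white, dark)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
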