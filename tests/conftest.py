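import dataclasses

import pytest

import pbshalo as p


@pytest.fixture(scope="session")
def model70():
    """Default two-Gaussian spot model for the lowest beam energy."""
    return p.default_spot_model(70, "Z0")


@pytest.fixture(scope="session")
def truth70(model70):
    return p.make_truth_image(model70, 5.0 * model70.outer_sigma)


@pytest.fixture(scope="session")
def gauss_model():
    """Pure Gaussian spot, sigma 5 mm."""
    return p.SpotModel(5.0)


@pytest.fixture(scope="session")
def gauss_truth(gauss_model):
    return p.make_truth_image(gauss_model, 25.0, 0.5)


@pytest.fixture()
def film_quiet():
    """Film device with noise switched off (deterministic oracle runs)."""
    return p.film_device(noise_fraction=0.0)


@pytest.fixture()
def shifted_truth(model70):
    def make(dx, dy):
        shifted = dataclasses.replace(model70, center=(dx, dy))
        return p.make_truth_image(shifted, 5.0 * model70.outer_sigma)
    return make
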