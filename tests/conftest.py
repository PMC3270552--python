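import numpy as np
import pytest

import echoreg as er


@pytest.fixture(scope="session")
def bundle():
    """Default 64-cube phantom fixture (identity ground truth)."""
    return er.make_registration_fixture(7)


@pytest.fixture(scope="session")
def prob_maps(bundle):
    """(us_map, mr_map) built through the standard pipeline on `bundle`."""
    return er.build_probability_maps(
        bundle.mr, bundle.us, bundle.lesion_mask, bundle.brain_mask
    )


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free 48-cube phantom (no speckle, no MR noise)."""
    return er.make_registration_fixture(
        11, shape=(48, 48, 48), mr_noise_sigma=0.0, us_speckle_var=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
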