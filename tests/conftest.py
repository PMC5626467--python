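import numpy as np
import pytest

from cortigrad import SyntheticSpec, TruthProfile, generate_midsagittal_image
from cortigrad.extraction import geometry_from_truth


@pytest.fixture(scope="session")
def noiseless_spec() -> SyntheticSpec:
    """Exponential cortical embryo with every noise source switched off."""
    return SyntheticSpec(
        photon_scale=np.inf,
        read_noise_sd=0.0,
        background_level=0.0,
        embryo_baseline=0.0,
        nuclei_count=0,
    )


@pytest.fixture(scope="session")
def noiseless_embryo(noiseless_spec):
    """(image, ground truth, exact geometry) for the noiseless embryo."""
    img, gt = generate_midsagittal_image(noiseless_spec)
    return img, gt, geometry_from_truth(gt)


@pytest.fixture(scope="session")
def default_embryo():
    """Default noisy embryo (autofluorescent baseline, nuclei, shot noise)."""
    spec = SyntheticSpec(rng_seed=11)
    img, gt = generate_midsagittal_image(spec)
    return img, gt


def exponential_profile_arrays(lam=20.0, amplitude=100.0, step=0.5):
    x = np.arange(0.0, 100.0 + 1e-9, step)
    return x, amplitude * np.exp(-x / lam)


@pytest.fixture()
def exp_profile():
    from cortigrad.extraction import IntensityProfile

    x, v = exponential_profile_arrays()
    return IntensityProfile(x, v)
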