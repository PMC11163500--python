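import numpy as np
import pytest

from smallfield.beam_model import DoseKernel, convolve_radial, top_hat


@pytest.fixture(scope="session")
def gaussian_kernel():
    """Unit-integral Gaussian kernel, sigma 0.5 mm, 0.1 mm sampling."""
    return DoseKernel.gaussian(0.5, spacing=0.1)


@pytest.fixture(scope="session")
def dose_3mm(gaussian_kernel):
    """3 mm top-hat convolved with the Gaussian kernel on a 0.1 mm grid."""
    return convolve_radial(top_hat(3.0), gaussian_kernel, spacing=0.1,
                           half_width=8.0)


@pytest.fixture(scope="session")
def dose_3mm_profile(dose_3mm):
    from smallfield.beam_model import extract_profile

    return extract_profile(dose_3mm, "x")


def mirror_radial(radii, values):
    """Reflect a radial function into a full signed-position profile."""
    positions = np.concatenate([-radii[::-1], radii[1:]])
    full = np.concatenate([values[::-1], values[1:]])
    return positions, full
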