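import numpy as np
import pytest

import gcscreen as g


@pytest.fixture
def calib2():
    """Two-alkane calibration: C10 at 600 s, C11 at 672 s."""
    return g.AlkaneCalibration(carbon=np.array([10, 11]), rt=np.array([600.0, 672.0]))


@pytest.fixture(scope="session")
def full_calib():
    """C7-C40 linear alkane schedule."""
    return g.default_calibration()


@pytest.fixture(scope="session")
def small_lib():
    return g.simulate_library(8, seed=123, richness_range=(4, 12))


def gaussian_eic(area, rt0=100.0, fwhm=3.0, scan_period=0.2, n=200, t0=80.0,
                 mz=150.05, mz_delta=0.05):
    """An EIC holding one Gaussian peak of the given trapezoidal area."""
    from scipy.stats import norm

    t = t0 + scan_period * np.arange(n)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    y = area * norm.pdf(t, loc=rt0, scale=sigma)
    return g.EIC(target_mz=mz, mz_delta=mz_delta, rts=t, intensities=y)


@pytest.fixture
def make_gaussian_eic():
    return gaussian_eic
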