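import numpy as np
import pytest
from hypothesis import settings

import flimmix as fm

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_instrument() -> fm.InstrumentConfig:
    """Small acquisition (256 bins / 80 ns, 4e3 photons) for fast unit tests."""
    return fm.InstrumentConfig(window_ns=80.0, n_photons=4_000)


@pytest.fixture(scope="session")
def bare_instrument() -> fm.InstrumentConfig:
    """No laser pulse, no jitter, no background: the pure exponential decay."""
    return fm.InstrumentConfig(
        laser_fwhm_ns=0.0,
        laser_turnoff_ns=0.0,
        jitter_sigma_ns=0.0,
        snr=None,
    )


def moment_lifetime(curve: fm.DecayCurve) -> float:
    """Closed-form lifetime estimator from the mean bin index of a pure
    exponential histogram: E[floor(t/w)] = 1/(exp(w/tau) - 1) for an
    unbounded window, inverted for tau.  Independent of the simulator's
    internals; valid when the window is much longer than tau."""
    w = curve.bin_width_ns
    k_mean = np.average(np.arange(len(curve.counts)), weights=curve.counts)
    return w / np.log1p(1.0 / k_mean)
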