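import numpy as np
import pytest

from scfret import simkit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_phys():
    """Noise-free, background-free photophysics for exactness checks."""
    return simkit.PhotophysicsParams(total_emission=1000.0, background_mean=0.0,
                                     noise_sd=0.0)


@pytest.fixture
def default_phys():
    """Study-condition noise level: E-domain width ~0.04 at 1000 counts."""
    return simkit.PhotophysicsParams(total_emission=1000.0,
                                     background_mean=100.0, noise_sd=50.0)


def make_traceset(donor, acceptor, excitation=None, frame_time=0.05,
                  background=(0.0, 0.0)):
    """Hand-built TraceSet for arithmetic unit tests."""
    from scfret.containers import TraceSet
    donor = np.atleast_2d(np.asarray(donor, dtype=float))
    if excitation is None:
        excitation = np.full(donor.shape[1], "green", dtype="U5")
    return TraceSet(frame_time=frame_time, excitation=np.asarray(excitation),
                    donor=donor, acceptor=acceptor, background=background)
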