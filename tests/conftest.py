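import numpy as np
import pytest

from pvspulse import dwi_forward as fwd
from pvspulse import synth_cohort as sc


@pytest.fixture(scope="session")
def pgse():
    return fwd.PGSEParams()


@pytest.fixture(scope="session")
def baseline_animal():
    """Preset-mean multidelay animal (baseline physiological state)."""
    return sc.preset_animal("multidelay")


@pytest.fixture(scope="session")
def cycle(baseline_animal):
    return baseline_animal.cycle


@pytest.fixture(scope="session")
def acq64():
    return fwd.AcquisitionParams(matrix=(64, 64, 2), ecg_delay=25.0)


@pytest.fixture(scope="session")
def phantom64(acq64):
    return fwd.make_phantom(acq64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
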