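import pytest

import vfadesign as vd


@pytest.fixture(scope="session")
def pulse():
    """Default slice-selective excitation; the Bloch profile cache is shared
    across the whole session."""
    return vd.RFPulse.hanning_sinc()


@pytest.fixture(scope="session")
def hard_pulse():
    return vd.RFPulse.hard_pulse()


@pytest.fixture(scope="session")
def liver_space():
    return vd.ParamSpace.liver_3t()
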