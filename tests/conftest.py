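import numpy as np
import pytest

from phasesmooth import RealSignal


@pytest.fixture
def tone():
    """Factory for a pure tone RealSignal."""

    def make(fc=10.0, fs=250.0, duration=8.0, amplitude=1.0, phase=0.0):
        t = np.arange(int(round(duration * fs))) / fs
        return RealSignal(amplitude * np.cos(2 * np.pi * fc * t + phase), fs=fs)

    return make
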