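import numpy as np
import pytest

from itemd.sifting import Signal, SiftConfig


FS = 512.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def sine_8hz():
    """Unit-amplitude 8 Hz sine, 10 s at 512 Hz."""
    t = np.arange(int(10 * FS)) / FS
    return Signal(np.sin(2 * np.pi * 8 * t), FS)


@pytest.fixture(scope="session")
def sine_10hz():
    t = np.arange(int(10 * FS)) / FS
    return Signal(np.sin(2 * np.pi * 10 * t), FS)


@pytest.fixture
def quick_config():
    """Shallow inner loop for structural tests that don't probe shape."""
    return SiftConfig(max_inner_sifts=20)
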