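import numpy as np
import pytest

from cheechlab import simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_kernel():
    return simulate.EvokedKernel()


@pytest.fixture(scope="session")
def n1_kernel_2048():
    """Kernel scaled so the target/masker [110,160) ms window means are the
    cohort-level condition means (−0.142 / +0.113 µV) at 2048 Hz."""
    return simulate.EvokedKernel().with_window_means(2048.0, -0.142, 0.113)


@pytest.fixture(scope="session")
def alternating_events():
    """20 well-separated first-chirp events alternating target/masker."""
    return [(0.5 + 0.7 * i, "target" if i % 2 == 0 else "masker") for i in range(20)]
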