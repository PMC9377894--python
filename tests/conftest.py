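import numpy as np
import pytest

import crcd


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def worked():
    return crcd.make_worked_example()


@pytest.fixture(scope="session")
def phantom_default():
    """One default phantom shared by read-only tests."""
    return crcd.make_phantom(crcd.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def disc_image():
    """Noise-free bright disc on dark ground with its truth mask."""
    rr, cc = np.mgrid[0:80, 0:80].astype(float)
    disc = np.hypot(rr - 40, cc - 40) <= 15
    return np.where(disc, 0.85, 0.1), disc
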