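import numpy as np
import pytest

from micropursuit import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_traj(x, y, rate=75.0, t0=0.0, mask=None):
    return Trajectory.from_xy(x, y, rate=rate, t0=t0, missing_mask=mask)


@pytest.fixture
def random_pair(rng):
    """A pair of smooth random trajectories sharing a grid."""

    def _make(n=200, rate=75.0, smooth=5):
        def sig():
            w = rng.standard_normal(n + 2 * smooth)
            k = np.hanning(2 * smooth + 1)
            return np.convolve(w, k / k.sum(), mode="same")[smooth:-smooth]

        a = make_traj(sig(), sig(), rate)
        b = make_traj(sig(), sig(), rate)
        return a, b

    return _make
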