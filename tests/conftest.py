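import numpy as np
import pytest

from bbbkit import Trajectory


@pytest.fixture
def toy_track():
    """Hand-enumerable 5-point staircase track at dt = 1 s."""
    return Trajectory(
        cell_id="toy",
        t=np.arange(5.0),
        x=np.array([0.0, 1.0, 1.0, 2.0, 2.0]),
        y=np.array([0.0, 0.0, 1.0, 1.0, 2.0]),
    )


@pytest.fixture
def straight_track():
    """Constant-velocity track: v = (2, 0) μm/s at dt = 1 s."""
    t = np.arange(50.0)
    return Trajectory(cell_id="straight", t=t, x=2.0 * t, y=np.zeros_like(t))


def brute_force_msd(x, y, k_max):
    """Independent oracle: double loop over all ordered frame pairs."""
    msd, pairs = [], []
    for k in range(1, k_max + 1):
        sq = [
            (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2
            for i in range(len(x) - k)
        ]
        msd.append(sum(sq) / len(sq))
        pairs.append(len(sq))
    return np.array(msd), np.array(pairs)
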