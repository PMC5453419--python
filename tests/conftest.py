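import numpy as np
import pytest

from freewalk import Trajectory, WalkerConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def straight_line():
    """Straight walk along +x at 10 mm/s, sampled every 1 s for 100 s."""
    t = np.arange(101.0)
    return Trajectory("line", "test", t, 10.0 * t, np.zeros_like(t),
                      fps_nominal=1.0)


@pytest.fixture
def hand_path():
    """Small irregular 5-point path used for arithmetic oracles."""
    t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    x = np.array([0.0, 3.0, 3.0, -1.0, 2.0])
    y = np.array([0.0, 4.0, 1.0, 1.0, 5.0])
    return Trajectory("hand", "test", t, x, y, fps_nominal=1.0)


def make_walker(kind, seed, **kw):
    return generate(WalkerConfig(kind=kind, seed=seed, **kw))
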