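import numpy as np
import pytest

from motorunit.kinematics import Track


def make_track(positions, dt=3.0, track_id="t0", **kw):
    positions = np.asarray(positions, dtype=float)
    times = dt * np.arange(positions.size)
    return Track(track_id, times, positions, **kw)


def track_from_speeds(speeds, dt=3.0, signs=None, track_id="t0", **kw):
    """Build a track whose per-step |Δx|/Δt equals the given speeds."""
    speeds = np.asarray(speeds, dtype=float)
    if signs is None:
        signs = np.ones_like(speeds)
    increments = signs * speeds * dt
    positions = np.concatenate([[0.0], np.cumsum(increments)])
    return make_track(positions, dt=dt, track_id=track_id, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
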