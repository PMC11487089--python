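import numpy as np
import pytest

from threemic import synthgen
from threemic.core import Track, TrackSet


@pytest.fixture(scope="session")
def brownian_900() -> TrackSet:
    """Reference well-nurtured-like ensemble: 900 tracks, 96 frames, 15 min."""
    spec = synthgen.WalkSpec(model="brownian", n_tracks=900, n_steps=96,
                             dt_min=15.0, step_scale_um=2.0, seed=20)
    return synthgen.make_tracks(spec)


@pytest.fixture(scope="session")
def ballistic_50() -> TrackSet:
    spec = synthgen.WalkSpec(model="ballistic", n_tracks=50, n_steps=96,
                             dt_min=15.0, step_scale_um=2.0, seed=21)
    return synthgen.make_tracks(spec)


def straight_track(track_id: int, net_um: float, n: int = 5,
                   dt: float = 15.0) -> Track:
    """A straight track along +x with the given net displacement."""
    t = np.arange(n) * dt
    x = np.linspace(0.0, net_um, n)
    return Track(track_id, t, x, np.zeros(n))
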