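import numpy as np
import pytest

from synkin.trackcore import Track, build_spot_grid


def make_track(positions, frame_interval=30.0, cell_id="t", channels=None, frames=None):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    frames = np.asarray(frames)
    return Track(
        cell_id=cell_id,
        frames=frames,
        times=(frames - frames[0]) * frame_interval,
        positions=positions,
        channels=channels or {},
        frame_interval=frame_interval,
    )


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid10():
    """10-μm spots, 30-μm square lattice over 90x90 μm (16 spots)."""
    return build_spot_grid(10.0, 30.0, (0.0, 0.0, 90.0, 90.0))
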