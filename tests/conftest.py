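import numpy as np
import pytest

from manimouse import ArenaGeometry, KeypointTrack

SEVEN_POINTS = (
    "nose", "left_ear", "right_ear", "neck", "body_center", "tail_base", "tail_tip"
)


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry(center=(400.0, 400.0), zone_radii=(60.0, 140.0, 220.0, 300.0))


def make_track(coords: np.ndarray, names=SEVEN_POINTS) -> KeypointTrack:
    """Wrap an (n_frames, K, 2) array as a KeypointTrack."""
    return KeypointTrack(coordinates=coords, keypoint_names=names)


@pytest.fixture
def random_track(arena) -> KeypointTrack:
    """A 200-frame random 7-point track with unit-spread ears around the center."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(200, 600, size=(200, len(SEVEN_POINTS), 2))
    return make_track(coords)
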