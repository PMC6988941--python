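import numpy as np
import pytest

from spvsim import PhospheneGridConfig


@pytest.fixture
def default_config():
    return PhospheneGridConfig()


@pytest.fixture
def small_config():
    """A 4x4 grid small enough for brute-force render oracles."""
    return PhospheneGridConfig(rows=4, cols=4, output_px=64, dropout_rate=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


# Room-identification outcome counts for the schematic method, 50 trials per
# room: rows = actual room (bathroom, bedroom, dining_room, kitchen,
# living_room, office), columns = predicted room in the same order plus a
# final not-answered column.
ROOM_ID_COUNTS = np.array(
    [
        [39, 0, 0, 0, 4, 1, 6],
        [0, 43, 0, 0, 1, 0, 6],
        [0, 0, 43, 1, 0, 1, 5],
        [1, 0, 0, 24, 1, 1, 23],
        [2, 1, 0, 0, 33, 2, 12],
        [5, 3, 0, 1, 0, 29, 12],
    ],
    dtype=np.int64,
)


@pytest.fixture
def room_id_counts():
    return ROOM_ID_COUNTS.copy()
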