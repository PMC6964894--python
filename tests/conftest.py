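import numpy as np
import pytest

import qtcmatch as q


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def scheme():
    return q.DEFAULT_SCHEME


@pytest.fixture
def two_player_fragment():
    """Two players converging then diverging; 10 samples at 25 Hz."""
    p1 = q.straight_run((0.0, 0.0), (1.0, 0.0), 6.0, 10, 25, "P1")
    p2 = q.straight_run((20.0, 0.0), (-1.0, 0.0), 6.0, 10, 25, "P2")
    return q.Fragment(0, (p1, p2))


@pytest.fixture
def diagonal_trio():
    """Three players with diagonal headings whose corner relations flip
    when the whole group is translated across the pitch."""
    return (
        q.straight_run((5.0, 5.0), (1.0, 1.0), 5.0, 8, 25, "P1"),
        q.straight_run((12.0, 5.0), (1.0, 0.4), 6.0, 8, 25, "P2"),
        q.straight_run((5.0, 12.0), (0.3, 1.0), 4.0, 8, 25, "P3"),
    )


@pytest.fixture
def small_recording(rng):
    """Recording of three 120-sample bounded random walks."""
    rec = {}
    for i in range(3):
        oid = f"P{i + 1}"
        rec[oid] = q.random_walk(
            100 + i, (30.0 + 10 * i, 30.0), 120, 0.3,
            bounds=(0.0, 105.0, 0.0, 68.0), object_id=oid,
        )
    return rec
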