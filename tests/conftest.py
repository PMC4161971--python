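import numpy as np
import pytest

from morphtrack import (
    AnalysisConfig,
    BehaviorParams,
    build_track_a,
    build_track_b,
    constant_schedule,
    make_configuration,
    simulate_trajectory,
)
from morphtrack.pipeline import simulate_session_a


@pytest.fixture(scope="session")
def track_a():
    return build_track_a()


@pytest.fixture(scope="session")
def track_b():
    return build_track_b()


@pytest.fixture(scope="session")
def small_session(track_a):
    """A small but complete Track A session (6 cells, 36 moves)."""
    return simulate_session_a(n_cells=6, anchoring="linear_fraction",
                              n_moves=36, seed=7)


@pytest.fixture(scope="session")
def straight_trajectory(track_a):
    """A 60 s trajectory on one frozen pose, for spiking/occupancy oracles."""
    cfg = make_configuration(track_a, 160.0, 160.0, config_id="frozen")
    sched = constant_schedule(track_a, cfg, 60.0)
    return simulate_trajectory(track_a, sched, BehaviorParams(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
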