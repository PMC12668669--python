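import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon

import patchforage as pf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def square_patch() -> Polygon:
    """Unit-free 2x2 mm square patch centred at the origin."""
    return Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])


@pytest.fixture(scope="session")
def arena() -> pf.ArenaGeometry:
    return pf.ArenaGeometry()


@pytest.fixture(scope="session")
def short_params() -> pf.SimWormParams:
    """Fast-mixing rates and a short recording for cheap end-to-end tests."""
    rates = pf.RateSet(k_FB=2.0, k_BO=2.0, k_OB=4.0, k_BF=4.0)
    return pf.SimWormParams(rates=rates, duration=120.0)


@pytest.fixture(scope="session")
def short_track(arena, short_params) -> pf.TrackRecording:
    seq = pf.simulate_state_sequence(short_params.rates, short_params.duration, "F", 7)
    return pf.render_track(seq, arena, short_params, seed=7)
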