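import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ringlane as rl

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geometry():
    return rl.RingGeometry()


@pytest.fixture(scope="session")
def small_population():
    """20 mobile cells, 24 h, defaults otherwise — shared read-only fixture."""
    params = rl.ctrl_like(n_cells=20, duration=24.0, immobile_fraction_true=0.0, seed=7)
    return rl.simulate_population(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_segments(spans, t0=0.0):
    """Build a tiling StateSegment list from (label, duration, direction) tuples."""
    segs = []
    t = t0
    for k, (label, dur, direction) in enumerate(spans):
        segs.append(
            rl.StateSegment(
                label=label,
                start=t,
                end=t + dur,
                direction=direction,
                first_frame=-1,
                last_frame=-1,
                starts_at_track_start=(k == 0),
                ends_at_track_end=(k == len(spans) - 1),
            )
        )
        t += dur
    return segs
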