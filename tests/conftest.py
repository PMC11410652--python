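import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import heatseek as hs
from heatseek.geometry import ArenaSpec, ZoneLayout

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_arena() -> ArenaSpec:
    """A scaled-down arena (same aspect ratio) that keeps unit tests fast."""
    return ArenaSpec(height_px=360, width_px=640, fps=10.0, duration_s=30.0)


@pytest.fixture(scope="session")
def small_layout(small_arena) -> ZoneLayout:
    return ZoneLayout.scaled(small_arena.height_px, small_arena.width_px)


@pytest.fixture(scope="session")
def rendered(small_arena, small_layout):
    """One simulated + rendered experiment with a 3:1 zone-2 preference.

    Shared across tests that need a realistic fixture: ground truth, the
    rendered frame stack, and the tracked/classified tables.
    """
    params = hs.BehaviorParams(
        n_mosquitoes=20,
        arrival_rate_zone1=0.025,
        arrival_rate_zone2=0.075,
        zones=small_layout,
    )
    truth = hs.simulate_ground_truth(small_arena, params, seed=3)
    frames = hs.render_frames(truth, small_arena, render_seed=4)
    return {"arena": small_arena, "layout": small_layout, "params": params,
            "truth": truth, "frames": frames}


@pytest.fixture(scope="session")
def tracked(rendered):
    """Tracks and classified observations recovered from the rendered fixture."""
    from heatseek import seek_filter, tracker

    arena = rendered["arena"]
    tracks = tracker.track_stack(rendered["frames"], seed=5)
    table = tracker.tracks_to_table(tracks, arena.fps)
    fparams = seek_filter.FilterParams()
    landed = seek_filter.area_filter(table, fparams)
    classified = seek_filter.classify_seeking(landed, fparams, arena.fps)
    return {"tracks": tracks, "table": table, "landed": landed,
            "classified": classified, "fparams": fparams}
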