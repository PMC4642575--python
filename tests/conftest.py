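import numpy as np
import pytest

from netflight.config import ArenaGeometry, ClassifierConfig
from netflight.model import TestRecord, Track
from netflight.regions import RegionMap
from netflight.simulate import GenerationParams, generate_test

TestRecord.__test__ = False  # dataclass, not a test class


@pytest.fixture(scope="session")
def config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def geometry():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def region_map(geometry):
    return RegionMap(geometry)


def make_track(x, y, track_id="t0", test_id="test0", frame_rate=50.0,
               start_frame=0):
    x = np.asarray(x, dtype=float)
    return Track(
        track_id=track_id, test_id=test_id,
        frames=start_frame + np.arange(len(x)),
        x=x, y=np.asarray(y, dtype=float),
        camera_field="both", frame_rate=frame_rate,
    )


@pytest.fixture(scope="session")
def small_test(config, geometry):
    """A scaled-down synthetic test (10 minutes, modest track rate) shared
    by tests that only need a realistic mixed-mode dataset."""
    params = GenerationParams(seed=42, net_type="untreated",
                              duration_s=600.0, tracks_per_bin=12.0)
    return generate_test(params, config, geometry)
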