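"""Shared fixtures: small synthetic tables and geometries built in memory."""

from datetime import datetime

import numpy as np
import pytest
from shapely.geometry import box

from remcam.types import Deployment, EventRecord, HabitatMap


@pytest.fixture
def small_deployments():
    start = datetime(2010, 8, 1, 0, 0)
    end = datetime(2010, 8, 11, 0, 0)  # 10 full days
    return [
        Deployment("c1", 1.0, 1.0, start, end, habitat="grassland"),
        Deployment("c2", 5.0, 1.0, start, end, habitat="woodland"),
    ]


@pytest.fixture
def split_habitat_map():
    # grassland: x in [0, 4); woodland: x in [4, 8)
    return HabitatMap(
        {
            "grassland": box(0.0, 0.0, 4.0, 8.0),
            "woodland": box(4.0, 0.0, 8.0, 8.0),
        }
    )


def make_events(camera_id, times, count=1):
    return [EventRecord(camera_id=camera_id, timestamp=t, count=count) for t in times]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
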