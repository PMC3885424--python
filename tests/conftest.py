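import numpy as np
import pandas as pd
import pytest

from tigertrack.synthetic import SimulationConfig, make_receivers, make_tag
from tigertrack.types import Detection, Receiver, TagDeployment

T0 = pd.Timestamp("2010-08-12T00:00:00Z")


@pytest.fixture
def short_config():
    """A 60-day resident simulation, cheap enough for unit tests."""
    return SimulationConfig(seed=11, duration_days=60, regime="resident")


@pytest.fixture
def receivers(short_config):
    return make_receivers(short_config)


@pytest.fixture
def tag(short_config):
    return make_tag(short_config)


def detections_on_days(day_offsets, tag_id="T001", receiver_id="R01",
                       t0=T0, hour=10):
    """One detection per listed day offset (UTC hour fixed)."""
    return [Detection(tag_id, receiver_id,
                      t0 + pd.Timedelta(days=int(d), hours=hour))
            for d in day_offsets]


def single_array(receiver_id="R01", lon=158.3, lat=-19.9, days=1500, t0=T0):
    return [Receiver(receiver_id, "array", lon, lat, 15.0, t0,
                     t0 + pd.Timedelta(days=days))]


def simple_tag(tag_id="T001", battery_days=1448, t0=T0, lon=158.3, lat=-19.9):
    from tigertrack.types import TAG_CONFIGS
    return TagDeployment(tag_id, "shark", "F", 300.0, "sub_adult",
                         "not_applicable", t0, lon, lat, battery_days,
                         TAG_CONFIGS[battery_days])
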