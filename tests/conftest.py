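import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def simple_stations():
    """Three planar stations, two blocks, 14-day deployments."""
    return pd.DataFrame({
        "station_id": ["A", "B", "C"],
        "x": [0.0, 1000.0, 2000.0],
        "y": [0.0, 0.0, 1000.0],
        "coord_system": ["planar"] * 3,
        "activation_date": pd.to_datetime(["2021-01-01"] * 3),
        "retrieval_date": pd.to_datetime(["2021-01-14"] * 3),
        "pir_delay_class": ["<=0.6s", ">0.6s", "<=0.6s"],
        "block_id": ["R1", "R1", "R2"],
    })


def make_records(rows):
    """rows: list of (station_id, species, iso timestamp)."""
    df = pd.DataFrame(rows, columns=["station_id", "species", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture
def record_factory():
    return make_records
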