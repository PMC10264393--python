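import datetime as dt

import pandas as pd
import pytest

from dragontherm import CANBERRA, PipelineConfig, run_field_campaign
from dragontherm.synthetic import MicroclimateParams, TraceParams


@pytest.fixture(scope="session")
def site():
    return CANBERRA


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def noisefree_trace_params():
    return TraceParams(sensor_noise_sd=0.0, signal_noise_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_micro_params():
    return MicroclimateParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def campaign():
    """One seeded synthetic tracking campaign shared across tests."""
    return run_field_campaign(seed=5)


def make_slots(t_trans, t_shade, t_burrow, signal=None, start="2013-01-05 00:00"):
    """One dragon-day of matched 10-min slots from plain lists."""
    n = len(t_trans)
    ts = pd.date_range(start, periods=n, freq="10min")
    data = {
        "dragon_id": "d01",
        "timestamp": ts,
        "t_trans": t_trans,
        "t_shade": t_shade if hasattr(t_shade, "__len__") else [t_shade] * n,
        "t_burrow": t_burrow if hasattr(t_burrow, "__len__") else [t_burrow] * n,
    }
    data["t_sun"] = [max(s + 10, t) for s, t in zip(data["t_shade"], data["t_trans"])]
    if signal is not None:
        data["signal_strength"] = signal
    return pd.DataFrame(data)
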