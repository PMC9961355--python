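import numpy as np
import pandas as pd
import pytest

from glyrisk.cgm_io import CGMSeries
from glyrisk.risk_scale import RiskSeries, glucose_to_risk

T0 = pd.Timestamp("2021-06-01 00:00:00")


def make_series(values, dt=5.0, individual_id="test", valid=None):
    return CGMSeries(individual_id, T0, dt, np.asarray(values, dtype=float), valid)


def make_risk_series(glucose, dt=5.0, individual_id="test"):
    return RiskSeries(individual_id, T0, dt, glucose_to_risk(np.asarray(glucose, dtype=float)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid_glucose():
    """Noiseless sinusoid: period 4 h (48 steps at 5 min), range 80-200 mg/dL."""
    t = np.arange(5000)
    return 140.0 + 60.0 * np.sin(2 * np.pi * t / 48.0)


@pytest.fixture
def simple_series():
    return make_series([100, 110, 120, 130, 125, 115])
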