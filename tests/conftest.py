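import numpy as np
import pandas as pd
import pytest

from aerodyn.timeseries import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def weekly_grid():
    """Three years of weekly Mondays."""
    return pd.date_range("2019-01-07", periods=157, freq="7D")


def make_weekly(values, name="x") -> TimeSeries:
    return TimeSeries("2019-01-07", 7.0, np.asarray(values, dtype=float),
                      name=name)


@pytest.fixture
def annual_sine():
    """Noiseless Y = 2 sin(2 pi t) sampled weekly for 3 years."""
    ts = make_weekly(np.zeros(157))
    return ts.copy_with(2.0 * np.sin(2 * np.pi * ts.t_years))
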