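import warnings

import numpy as np
import pandas as pd
import pytest

import climuq as cq
from climuq.indices import BasePeriodPercentiles


@pytest.fixture(scope="session")
def truth_tn():
    return cq.make_truth("temperate_north", 1)


@pytest.fixture(scope="session")
def truth_ts():
    return cq.make_truth("tropical_south", 1)


@pytest.fixture(scope="session")
def ref20(truth_tn):
    """20-year temperate reference series."""
    return cq.simulate_series(truth_tn, n_years=20, seed=3, site_id="tn")


@pytest.fixture(scope="session")
def ref20_south(truth_ts):
    return cq.simulate_series(truth_ts, n_years=20, seed=4, site_id="ts")


@pytest.fixture(scope="session")
def base20(ref20):
    return BasePeriodPercentiles.from_series(ref20)


@pytest.fixture(scope="session")
def battery20(ref20, base20):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cq.index_battery(ref20, base20, label="reference")


def make_series(tmax, tmin, prcp, start="2001-01-01", site_id="t", latitude=45.0):
    """Construct a DailySeries from plain arrays."""
    n = len(tmax)
    dates = pd.date_range(start, periods=n, freq="D")
    return cq.DailySeries(site_id=site_id, latitude=latitude, dates=dates,
                          tmax=np.asarray(tmax, float),
                          tmin=np.asarray(tmin, float),
                          prcp=np.asarray(prcp, float))


@pytest.fixture(scope="session")
def series_factory():
    return make_series
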