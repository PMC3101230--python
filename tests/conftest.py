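import numpy as np
import pandas as pd
import pytest


def make_records(station_id="S1", start="1973-01-01", n_days=365, tmin=2.0, tmax=12.0, prcp=0.0):
    """A simple constant daily record for one station."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {"station_id": station_id, "date": dates, "tmin": tmin, "tmax": tmax, "prcp": prcp}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def toy_world(tmp_path_factory):
    """A small synthetic world bundle shared by pipeline-level tests."""
    from winterchill.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("toy_world")
    paths = make_fixtures(seed=7, out_dir=out, n_stations=3, n_years=21)
    return paths
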