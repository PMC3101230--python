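"""Monthly aggregation, trend regressions and scenario construction."""

import numpy as np
import pandas as pd
import pytest

from winterchill import scenarios
from winterchill.scenarios import ClimateScenario
from conftest import make_records


def _monthly_series(slope=0.05, intercept=3.0, start=1973, n_years=30, noise_sd=0.0, rng=None):
    """30 years of daily records whose January means follow a known line."""
    frames = []
    for year in range(start, start + n_years):
        val = intercept + slope * (year - start)
        if noise_sd and rng is not None:
            val = val + rng.normal(0, noise_sd)
        frames.append(make_records("S1", start=f"{year}-01-01", n_days=365, tmin=val, tmax=val + 10))
    return pd.concat(frames, ignore_index=True)


def test_monthly_aggregate_constant_month():
    recs = make_records(n_days=31, tmin=2.0)
    monthly = scenarios.monthly_aggregate(recs)
    assert len(monthly) == 1
    assert monthly.loc[0, "mean_tmin"] == pytest.approx(2.0)


def test_monthly_aggregate_majority_missing_is_missing():
    recs = make_records(n_days=31)
    recs.loc[:19, "tmin"] = np.nan  # 20 of 31 missing
    monthly = scenarios.monthly_aggregate(recs)
    assert np.isnan(monthly.loc[0, "mean_tmin"])
    assert np.isfinite(monthly.loc[0, "mean_tmax"])


def test_monthly_aggregate_row_count_30_years():
    recs = make_records(start="1973-01-01", n_days=30 * 365 + 7)  # 30 full years
    monthly = scenarios.monthly_aggregate(recs)
    per_station = monthly.groupby("station_id").size()
    assert per_station["S1"] >= 360


def test_trend_exact_line_recovery():
    recs = _monthly_series(slope=0.05, intercept=3.0)
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    jan_tmin = trends[(trends["month"] == 1) & (trends["variable"] == "tmin")].iloc[0]
    assert jan_tmin["slope"] == pytest.approx(0.05, abs=1e-9)
    assert jan_tmin["slope"] * 1973 + jan_tmin["intercept"] == pytest.approx(3.0, abs=1e-6)
    assert jan_tmin["n_years"] == 30


def test_trend_constant_series_zero_slope():
    recs = _monthly_series(slope=0.0)
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    assert np.allclose(trends["slope"], 0.0, atol=1e-10)


def test_trend_too_few_years_emits_nothing():
    recs = _monthly_series(n_years=2)
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    assert trends.empty


def test_scenario_zero_trend_is_identity():
    recs = _monthly_series(slope=0.0, n_years=30)
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    calib = scenarios.calibration_means(monthly, 1973, 2002)
    scen = scenarios.scenario_at_year(trends, calib, 2000)
    assert np.allclose(scen.delta_tmin, 0.0, atol=1e-9)
    assert np.allclose(scen.delta_tmax, 0.0, atol=1e-9)
    assert np.allclose(scen.precip_factor, 1.0)


def test_scenario_delta_arithmetic_and_linearity():
    """Slope 0.04 °C/yr with calibration centred on 1987.5 gives +0.5 °C at
    2000, and the 1975/2000 deltas differ by exactly 25 * slope."""
    recs = _monthly_series(slope=0.04, intercept=3.0)
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    calib = scenarios.calibration_means(monthly, 1973, 2002)
    s2000 = scenarios.scenario_at_year(trends, calib, 2000)
    s1975 = scenarios.scenario_at_year(trends, calib, 1975)
    assert s2000.delta_tmin[0] == pytest.approx(0.04 * (2000 - 1987.5), abs=1e-6)
    assert np.allclose(s2000.delta_tmin - s1975.delta_tmin, 25 * 0.04, atol=1e-6)


def test_scenario_affine_in_slopes():
    recs = _monthly_series(slope=0.04)
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    calib = scenarios.calibration_means(monthly, 1973, 2002)
    base = scenarios.scenario_at_year(trends, calib, 2000)
    scaled = trends.copy()
    # rescale slopes about the calibration-mean pivot (keep prediction at mean year)
    c = 3.0
    mean_year = 1987.5
    scaled["intercept"] += (1 - c) * scaled["slope"] * mean_year
    scaled["slope"] *= c
    out = scenarios.scenario_at_year(scaled, calib, 2000)
    assert np.allclose(out.delta_tmin, c * base.delta_tmin, atol=1e-6)


def test_scenario_missing_month_error():
    recs = _monthly_series()
    monthly = scenarios.monthly_aggregate(recs)
    trends = scenarios.fit_monthly_trends(monthly, 1973, 2002)
    calib = scenarios.calibration_means(monthly, 1973, 2002)
    with pytest.raises(ValueError, match=r"\[7\]"):
        scenarios.scenario_at_year(trends[trends["month"] != 7], calib, 2000)


def _eighteen(seed=0):
    from winterchill.pipeline import make_future_scenarios

    return make_future_scenarios(seed)


def test_anomaly_table_roundtrip(tmp_path):
    scens = _eighteen()
    path = tmp_path / "anoms.csv"
    scenarios.write_anomaly_table(scens, path)
    loaded = scenarios.load_anomaly_table(path)
    assert len(loaded) == 18
    for a, b in zip(scens, loaded):
        assert a.label == b.label and a.epoch == b.epoch and a.ghg == b.ghg and a.gcm == b.gcm
        assert np.allclose(a.delta_tmin, b.delta_tmin)
        assert np.allclose(a.precip_factor, b.precip_factor)


def test_anomaly_table_bad_month_rejected(tmp_path):
    path = tmp_path / "anoms.csv"
    scenarios.write_anomaly_table(_eighteen()[:1], path)
    df = pd.read_csv(path)
    df.loc[0, "month"] = 13
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="months 1-12"):
        scenarios.load_anomaly_table(path)


def test_all_zero_anomalies_equal_baseline(tmp_path):
    path = tmp_path / "anoms.csv"
    scenarios.write_anomaly_table([ClimateScenario.zero("z")], path)
    (scen,) = scenarios.load_anomaly_table(path)
    assert np.allclose(scen.delta_tmin, 0) and np.allclose(scen.precip_factor, 1)
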