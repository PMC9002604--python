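"""Daily averaging QC, forecaster recovery, and MAE scoring."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from trusscast.thermal import (
    DailySeries,
    ForecastHyperparameters,
    ForecastModel,
    QCConfig,
    daily_average,
    fit_forecaster,
    forecast,
    mae,
    monthly_mae,
)


def records_for_day(day, values, cadence_min=5):
    start = datetime(2020, 6, day)
    return [(start + timedelta(minutes=cadence_min * i), v) for i, v in enumerate(values)]


# ------------------------------------------------------------ daily_average


def test_constant_records_give_constant_days():
    recs = records_for_day(1, [20.0] * 288) + records_for_day(2, [20.0] * 288)
    ds = daily_average(recs)
    assert list(ds.values) == [20.0, 20.0]
    assert ds.observed.all()


def test_half_missing_day_still_observed_at_default_coverage():
    recs = records_for_day(1, [18.0] * 144)  # half the 288 expected records
    ds = daily_average(recs)
    assert ds.values[0] == pytest.approx(18.0)
    assert ds.observed[0]
    # below the 25% floor the day is masked
    sparse = daily_average(records_for_day(1, [18.0] * 50))
    assert not sparse.observed[0]


def test_range_qc_removes_spike():
    vals = [20.0] * 287 + [-45.0]
    ds = daily_average(records_for_day(1, vals))
    assert ds.values[0] == pytest.approx(20.0)


def test_mad_qc_removes_in_range_outlier():
    vals = [20.0 + 0.01 * np.sin(i) for i in range(287)] + [55.0]
    ds = daily_average(records_for_day(1, vals))
    assert ds.values[0] == pytest.approx(20.0, abs=0.05)


def test_daily_average_permutation_invariant(rng):
    recs = records_for_day(1, list(rng.normal(20, 3, 288)))
    shuffled = [recs[i] for i in rng.permutation(len(recs))]
    a, b = daily_average(recs), daily_average(shuffled)
    assert a.values[0] == pytest.approx(b.values[0])


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        daily_average([])


def test_gap_days_present_but_masked():
    recs = records_for_day(1, [20.0] * 288) + records_for_day(3, [22.0] * 288)
    ds = daily_average(recs)
    assert len(ds) == 3
    assert not ds.observed[1]
    assert np.isnan(ds.values[1])


# ------------------------------------------------------------ forecaster


def daily_series(start, values):
    idx = pd.date_range(start, periods=len(values), freq="D")
    vals = np.asarray(values, dtype=float)
    return DailySeries(idx, vals, ~np.isnan(vals))


def test_constant_series_forecasts_constant():
    s = daily_series("2019-01-01", [20.0] * 400)
    m = fit_forecaster(s)
    pred = forecast(m, pd.date_range("2020-06-01", periods=30, freq="D"))
    assert np.allclose(pred.values, 20.0, atol=0.2)


def test_sinusoid_recovered_one_year_ahead():
    idx = pd.date_range("2018-01-01", "2019-12-31", freq="D")
    days = np.arange(len(idx), dtype=float)
    y = 15 + 10 * np.sin(2 * np.pi * days / 365.25)
    m = fit_forecaster(DailySeries(idx, y, np.ones(len(idx), bool)))
    fut = pd.date_range("2020-01-01", "2020-12-31", freq="D")
    d2 = (fut - idx[0]).days.to_numpy(dtype=float)
    truth = pd.Series(15 + 10 * np.sin(2 * np.pi * d2 / 365.25), index=fut)
    assert mae(forecast(m, fut), truth) < 0.5


def test_seasonal_amplitude_and_phase_recovered():
    idx = pd.date_range("2018-01-01", "2019-12-31", freq="D")
    days = np.arange(len(idx), dtype=float)
    y = 15 + 10 * np.sin(2 * np.pi * days / 365.25)
    m = fit_forecaster(DailySeries(idx, y, np.ones(len(idx), bool)))
    # params layout: [intercept, slope, deltas..., sin1, cos1, sin2, ...]
    n_trend = 2 + len(m.changepoints)
    s1, c1 = m.params[n_trend], m.params[n_trend + 1]
    amp = np.hypot(s1, c1)
    assert amp == pytest.approx(10.0, rel=0.05)
    # phase: pure sine at the epoch means cos coefficient ~0
    assert abs(np.arctan2(c1, s1)) < 0.05


def test_noisy_sinusoid_out_of_sample_mae_bounded(rng):
    idx = pd.date_range("2018-01-01", "2019-12-31", freq="D")
    days = np.arange(len(idx), dtype=float)
    clean = 15 + 10 * np.sin(2 * np.pi * days / 365.25)
    y = clean + rng.normal(0, 2.0, len(idx))
    m = fit_forecaster(DailySeries(idx, y, np.ones(len(idx), bool)))
    fut = pd.date_range("2020-01-01", "2020-12-31", freq="D")
    d2 = (fut - idx[0]).days.to_numpy(dtype=float)
    truth = pd.Series(15 + 10 * np.sin(2 * np.pi * d2 / 365.25), index=fut)
    assert mae(forecast(m, fut), truth) < 4.0  # within 2x the noise scale


def test_fit_is_deterministic():
    idx = pd.date_range("2019-01-01", periods=500, freq="D")
    y = 18 + 6 * np.cos(2 * np.pi * np.arange(500) / 365.25) + np.sin(np.arange(500))
    s = DailySeries(idx, y, np.ones(500, bool))
    m1, m2 = fit_forecaster(s), fit_forecaster(s)
    assert np.array_equal(m1.params, m2.params)
    assert m1.to_json() == m2.to_json()


def test_forecast_bounded_by_trend_caps_plus_seasonality():
    idx = pd.date_range("2018-01-01", "2019-12-31", freq="D")
    days = np.arange(len(idx), dtype=float)
    y = 15 + 10 * np.sin(2 * np.pi * days / 365.25)
    m = fit_forecaster(DailySeries(idx, y, np.ones(len(idx), bool)))
    fut = pd.date_range("2020-01-01", "2030-12-31", freq="D")  # extreme extrapolation
    pred = m.predict(fut)
    n_trend = 2 + len(m.changepoints)
    seas_amp = np.sum(np.abs(m.params[n_trend:]))
    assert pred.min() >= m.floor - seas_amp
    assert pred.max() <= m.cap + seas_amp


def test_missing_days_tolerated_and_all_missing_rejected():
    vals = [20.0] * 200
    vals[50:60] = [np.nan] * 10
    s = daily_series("2019-01-01", vals)
    m = fit_forecaster(s)
    assert np.isfinite(m.params).all()
    empty = DailySeries(
        pd.date_range("2019-01-01", periods=5, freq="D"),
        np.full(5, np.nan),
        np.zeros(5, bool),
    )
    with pytest.raises(ValueError):
        fit_forecaster(empty)


def test_predict_before_epoch_rejected():
    s = daily_series("2019-06-01", [20.0] * 100)
    m = fit_forecaster(s)
    with pytest.raises(ValueError):
        m.predict(pd.DatetimeIndex(["2019-01-01"]))


def test_model_json_round_trip(tmp_path):
    s = daily_series("2019-01-01", list(20 + np.sin(np.arange(120) / 10)))
    m = fit_forecaster(s)
    path = tmp_path / "model.json"
    m.to_json(path)
    m2 = ForecastModel.from_json(path)
    fut = pd.date_range("2019-06-01", periods=20, freq="D")
    assert np.allclose(m.predict(fut), m2.predict(fut))


# ------------------------------------------------------------ MAE


def test_mae_examples():
    idx = pd.date_range("2020-01-01", periods=2, freq="D")
    assert mae(pd.Series([21.0, 23.0], index=idx), pd.Series([20.0, 22.0], index=idx)) == 1.0
    assert mae([5.0], [5.0]) == 0.0
    assert mae([7.5], [5.0]) == 2.5


def test_mae_properties(rng):
    a, b = rng.normal(size=50), rng.normal(size=50)
    assert mae(a, b) == pytest.approx(mae(b, a))
    assert mae(a, a) == 0.0
    assert mae(a, b) >= 0
    with pytest.raises(ValueError):
        mae([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        mae([], [])


def test_monthly_mae_partition():
    idx = pd.date_range("2020-05-01", "2020-07-31", freq="D")
    actual = pd.Series(20.0, index=idx)
    pred = actual.copy()
    pred[idx.month == 6] += 2.0
    out = monthly_mae(pred, actual)
    assert out == {5: 0.0, 6: 2.0, 7: 0.0}
    one_day = pd.Series([20.0], index=pd.DatetimeIndex(["2020-03-15"]))
    assert monthly_mae(one_day + 1, one_day) == {3: 1.0}
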