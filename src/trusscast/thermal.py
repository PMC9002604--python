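"""Greenhouse temperature processing and seasonal forecasting.

Raw sensor logs arrive at ~5-min cadence and carry outliers (sensor
glitches) and missing spans (power outages).  :func:`daily_average`
reduces them to a quality-controlled daily-mean series; the
:class:`ForecastModel` is a self-contained additive model — a
changepoint-regularized piecewise-linear trend saturated between a
floor and a capacity, plus yearly Fourier seasonality — fit by
penalized least squares on the observed days.  Forecast skill is scored
by mean absolute error (MAE), overall or by calendar month.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "QCConfig",
    "DailySeries",
    "ForecastHyperparameters",
    "ForecastModel",
    "daily_average",
    "fit_forecaster",
    "forecast",
    "mae",
    "monthly_mae",
]

YEAR_DAYS = 365.25


@dataclass(frozen=True)
class QCConfig:
    """Quality-control rules applied before daily averaging.

    Records outside ``[range_lo, range_hi]`` degrees C are discarded;
    surviving records further than ``mad_k`` scaled median absolute
    deviations from their day's median are discarded; a day with fewer
    than ``min_coverage`` of its expected records is marked missing.
    """

    range_lo: float = -10.0
    range_hi: float = 60.0
    mad_k: float = 5.0
    min_coverage: float = 0.25
    cadence_min: int = 5

    @property
    def expected_per_day(self) -> int:
        return (24 * 60) // self.cadence_min


@dataclass
class DailySeries:
    """Contiguous date-indexed daily mean temperatures with missing mask.

    ``values`` holds NaN where ``observed`` is False; the index is
    strictly increasing with no gaps (missing days are present but
    masked).
    """

    index: pd.DatetimeIndex
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.index = pd.DatetimeIndex(self.index).normalize()
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not (len(self.index) == len(self.values) == len(self.observed)):
            raise ValueError("index, values and observed must have equal length")
        if len(self.index) > 1:
            deltas = np.diff(self.index.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("daily series index must be contiguous calendar days")

    def __len__(self) -> int:
        return len(self.index)

    @classmethod
    def from_mapping(cls, day_means: Mapping, fill_gaps: bool = True) -> "DailySeries":
        s = pd.Series(dict(day_means))
        s.index = pd.DatetimeIndex(s.index).normalize()
        s = s.sort_index()
        if fill_gaps and len(s) > 1:
            full = pd.date_range(s.index[0], s.index[-1], freq="D")
            s = s.reindex(full)
        return cls(s.index, s.to_numpy(dtype=float), ~np.isnan(s.to_numpy(dtype=float)))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name="mean_c")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.index.strftime("%Y-%m-%d"), "mean_c": self.values, "observed": self.observed}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DailySeries":
        df = pd.read_csv(path)
        idx = pd.DatetimeIndex(pd.to_datetime(df["date"]))
        return cls(idx, df["mean_c"].to_numpy(dtype=float), df["observed"].to_numpy(dtype=bool))


def daily_average(records, qc: QCConfig | None = None) -> DailySeries:
    """Reduce raw (timestamp, temp_c) records to QC'd daily means.

    Parameters
    ----------
    records : DataFrame with columns ``timestamp``/``temp_c``, or an
        iterable of ``(timestamp, value)`` pairs.
    qc : QCConfig, optional
    """
    qc = qc or QCConfig()
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns={records.columns[0]: "timestamp", records.columns[1]: "temp_c"})
        df = df[["timestamp", "temp_c"]].copy()
    else:
        rows = list(records)
        if not rows:
            raise ValueError("no temperature records supplied")
        df = pd.DataFrame(rows, columns=["timestamp", "temp_c"])
    if df.empty:
        raise ValueError("no temperature records supplied")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp")
    df = df[(df["temp_c"] >= qc.range_lo) & (df["temp_c"] <= qc.range_hi)]
    if df.empty:
        raise ValueError("no temperature records survive range QC")
    df["date"] = df["timestamp"].dt.normalize()

    def _day_mean(vals: pd.Series) -> tuple[float, int]:
        x = vals.to_numpy(dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > 0:
            x = x[np.abs(x - med) <= qc.mad_k * 1.4826 * mad]
        return float(np.mean(x)), len(x)

    stats = {d: _day_mean(g["temp_c"]) for d, g in df.groupby("date")}
    full = pd.date_range(min(stats), max(stats), freq="D")
    values = np.full(len(full), np.nan)
    observed = np.zeros(len(full), dtype=bool)
    min_n = qc.min_coverage * qc.expected_per_day
    for i, d in enumerate(full):
        if d in stats:
            mean, n = stats[d]
            if n >= min_n:
                values[i] = mean
                observed[i] = True
    return DailySeries(full, values, observed)


@dataclass(frozen=True)
class ForecastHyperparameters:
    """Additive-model hyperparameters.

    ``changepoint_prior_scale`` is the Laplace scale of the trend-slope
    changes (smaller = stiffer trend); ``yearly_order`` the number of
    Fourier harmonics of the 365.25-day cycle; capacity and floor of
    the saturating trend default to the training range +/- ``cap_pad_c``.
    ``interval_width`` is retained as metadata only (intervals are not
    produced).
    """

    changepoint_prior_scale: float = 0.01
    n_changepoints: int = 25
    changepoint_range: float = 0.8
    yearly_order: int = 10
    cap_pad_c: float = 5.0
    interval_width: float = 0.95
    growth: str = "logistic"


@dataclass
class ForecastModel:
    """Fitted additive seasonal model of daily mean temperature."""

    epoch: pd.Timestamp
    t_scale: float
    changepoints: np.ndarray  # in scaled time
    params: np.ndarray  # [intercept, slope, deltas..., fourier...]
    floor: float
    cap: float
    yearly_order: int
    hp: ForecastHyperparameters = field(default_factory=ForecastHyperparameters)

    def _design(self, t: np.ndarray, days: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(t), t]
        for s in self.changepoints:
            cols.append(np.maximum(0.0, t - s))
        for k in range(1, self.yearly_order + 1):
            w = 2.0 * np.pi * k * days / YEAR_DAYS
            cols.append(np.sin(w))
            cols.append(np.cos(w))
        return np.column_stack(cols)

    def _times(self, index: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
        days = (index.normalize() - self.epoch).days.to_numpy(dtype=float)
        return days / self.t_scale, days

    def predict(self, index: pd.DatetimeIndex) -> np.ndarray:
        """Deterministic daily-mean predictions for the given dates."""
        index = pd.DatetimeIndex(index).normalize()
        t, days = self._times(index)
        if np.any(days < 0):
            raise ValueError("cannot predict before the model epoch")
        n_trend = 2 + len(self.changepoints)
        X = self._design(t, days)
        trend = X[:, :n_trend] @ self.params[:n_trend]
        trend = np.clip(trend, self.floor, self.cap)  # saturating growth
        seasonal = X[:, n_trend:] @ self.params[n_trend:]
        return trend + seasonal

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "epoch": self.epoch.strftime("%Y-%m-%d"),
                "t_scale": self.t_scale,
                "changepoints": self.changepoints.tolist(),
                "params": self.params.tolist(),
                "floor": self.floor,
                "cap": self.cap,
                "yearly_order": self.yearly_order,
                "hp": {
                    "changepoint_prior_scale": self.hp.changepoint_prior_scale,
                    "n_changepoints": self.hp.n_changepoints,
                    "changepoint_range": self.hp.changepoint_range,
                    "yearly_order": self.hp.yearly_order,
                    "cap_pad_c": self.hp.cap_pad_c,
                    "interval_width": self.hp.interval_width,
                    "growth": self.hp.growth,
                },
            }
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "ForecastModel":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            epoch=pd.Timestamp(d["epoch"]),
            t_scale=float(d["t_scale"]),
            changepoints=np.asarray(d["changepoints"], dtype=float),
            params=np.asarray(d["params"], dtype=float),
            floor=float(d["floor"]),
            cap=float(d["cap"]),
            yearly_order=int(d["yearly_order"]),
            hp=ForecastHyperparameters(**d["hp"]),
        )


def fit_forecaster(
    series: DailySeries, hp: ForecastHyperparameters | None = None
) -> ForecastModel:
    """Fit the additive model to observed days of a daily series.

    Trend slope changes carry a smoothed-L1 penalty with scale
    ``changepoint_prior_scale`` (the Laplace-prior MAP objective);
    everything else is ordinary least squares.  Missing days are simply
    absent from the fit.  The optimization is deterministic: fixed zero
    initialization, L-BFGS-B with analytic gradients.
    """
    hp = hp or ForecastHyperparameters()
    obs = series.observed
    if not obs.any():
        raise ValueError("cannot fit a forecaster to an all-missing series")
    y = series.values[obs]
    days_all = (series.index - series.index[0]).days.to_numpy(dtype=float)
    days = days_all[obs]
    t_scale = max(days_all[-1], 1.0)
    t = days / t_scale

    # candidate changepoints: evenly spaced over the first changepoint_range
    # of observed history (skipping the very start)
    n_cp = hp.n_changepoints if len(y) > hp.n_changepoints else 0
    if n_cp > 0:
        cps = np.linspace(0.0, hp.changepoint_range * t.max(), n_cp + 1)[1:]
    else:
        cps = np.array([])

    floor = float(np.min(y) - hp.cap_pad_c)
    cap = float(np.max(y) + hp.cap_pad_c)

    model = ForecastModel(
        epoch=series.index[0],
        t_scale=t_scale,
        changepoints=cps,
        params=np.zeros(2 + len(cps) + 2 * hp.yearly_order),
        floor=floor,
        cap=cap,
        yearly_order=hp.yearly_order,
        hp=hp,
    )
    X = model._design(t, days)
    n = len(y)
    delta_sl = slice(2, 2 + len(cps))
    lam = 1.0 / (hp.changepoint_prior_scale * n)
    eps = 1e-8

    def objective(beta: np.ndarray) -> tuple[float, np.ndarray]:
        r = X @ beta - y
        f = 0.5 * float(r @ r) / n
        g = (X.T @ r) / n
        d = beta[delta_sl]
        sa = np.sqrt(d * d + eps)
        f += lam * float(np.sum(sa - np.sqrt(eps)))
        g[delta_sl] += lam * d / sa
        return f, g

    x0 = np.zeros(X.shape[1])
    x0[0] = float(np.mean(y))
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    model.params = res.x
    return model


def forecast(model: ForecastModel, dates: Iterable | pd.DatetimeIndex) -> pd.Series:
    """Predict daily means on a date range (no gaps)."""
    index = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    return pd.Series(model.predict(index), index=index, name="forecast_c")


def _aligned(pred, actual) -> tuple[np.ndarray, np.ndarray, pd.DatetimeIndex | None]:
    p = np.asarray(pred.values if isinstance(pred, pd.Series) else pred, dtype=float)
    a = np.asarray(actual.values if isinstance(actual, pd.Series) else actual, dtype=float)
    if len(p) != len(a):
        raise ValueError(f"series length mismatch: {len(p)} vs {len(a)}")
    if len(p) == 0:
        raise ValueError("MAE of empty series is undefined")
    idx = None
    if isinstance(pred, pd.Series) and isinstance(actual, pd.Series):
        if not pred.index.equals(actual.index):
            raise ValueError("series indexes are not aligned")
        idx = pd.DatetimeIndex(pred.index)
    return p, a, idx


def mae(pred, actual) -> float:
    """Mean absolute error between aligned series, in degrees C."""
    p, a, _ = _aligned(pred, actual)
    return float(np.mean(np.abs(p - a)))


def monthly_mae(pred: pd.Series, actual: pd.Series) -> dict[int, float]:
    """MAE restricted to each calendar month present (keys 1-12)."""
    p, a, idx = _aligned(pred, actual)
    if idx is None:
        raise ValueError("monthly MAE needs date-indexed series")
    err = pd.Series(np.abs(p - a), index=idx)
    return {int(m): float(v) for m, v in err.groupby(idx.month).mean().items()}
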