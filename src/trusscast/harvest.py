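"""Integrated-temperature harvest prediction and evaluation.

Harvest readiness is tied to thermal time: the integrated temperature
is the inclusive sum of daily mean temperatures from the anthesis date
(the bloom day is day i = 0 and contributes).  A truss's harvest
window runs from the first day the cumulative sum reaches the lower
threshold (1100 degree-days by default) to the last day it stays at or
below the upper threshold (1200), the range reported for the 'Momotaro
York' fresh-market cultivar.  For a constant daily mean T this reduces
to ceil(lo/T) - 1 <= n <= floor(hi/T) - 1 days after bloom.

Fruit-count prediction simply excludes tracks that dropped or never
set fruit; harvest-date predictions are scored against recorded dates
by mean absolute error in days, per truss and overall, labeled with
the forecast lead time that produced them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from trusscast.thermal import DailySeries, ForecastModel
from trusscast.tracking import COMPLETED, FRUIT, TrussState

__all__ = [
    "IntegrationRule",
    "HarvestPrediction",
    "HarvestEval",
    "integrated_temperature",
    "harvest_window",
    "predict_fruit_count",
    "daily_harvest_schedule",
    "evaluate_harvest",
]


@dataclass(frozen=True)
class IntegrationRule:
    """Degree-day thresholds bounding the harvest window."""

    lo: float = 1100.0
    hi: float = 1200.0

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi):
            raise ValueError(f"need 0 < lo <= hi, got lo={self.lo}, hi={self.hi}")


@dataclass(frozen=True)
class HarvestPrediction:
    """Per-truss harvest window and expected fruit count."""

    plant: int
    truss: int
    earliest: date
    latest: date
    fruit_count: int
    bloom_dates_used: tuple[date, ...] = ()

    def __post_init__(self) -> None:
        if self.earliest > self.latest:
            raise ValueError("earliest harvest date must not exceed latest")
        if self.fruit_count < 0:
            raise ValueError("fruit count must be non-negative")

    @property
    def midpoint(self) -> date:
        return self.earliest + timedelta(days=(self.latest - self.earliest).days // 2)

    def representative(self, which: str = "midpoint") -> date:
        return {"earliest": self.earliest, "midpoint": self.midpoint, "latest": self.latest}[which]


@dataclass(frozen=True)
class HarvestEval:
    """Harvest-date MAE in days, by truss and overall, at one lead time."""

    per_truss_mae: dict[tuple[int, int], float]
    overall_mae: float
    lead_weeks: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "lead_weeks": self.lead_weeks,
                "overall_mae": self.overall_mae,
                "per_truss_mae": {f"{p}_{t}": v for (p, t), v in self.per_truss_mae.items()},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _series_lookup(series) -> pd.Series:
    if isinstance(series, DailySeries):
        return series.to_series()
    if isinstance(series, pd.Series):
        s = series.copy()
        s.index = pd.DatetimeIndex(s.index).normalize()
        return s
    raise TypeError(f"expected DailySeries or pandas Series, got {type(series)}")


def integrated_temperature(series, bloom: date, end: date) -> float:
    """Inclusive degree-day sum from the bloom date through ``end``.

    The bloom day itself is day i = 0 and contributes to the sum.
    Raises if any date in [bloom, end] is uncovered, naming the first gap.
    """
    if bloom > end:
        raise ValueError(f"bloom date {bloom} is after end date {end}")
    s = _series_lookup(series)
    wanted = pd.date_range(pd.Timestamp(bloom), pd.Timestamp(end), freq="D")
    vals = s.reindex(wanted)
    missing = vals.index[vals.isna()]
    if len(missing):
        raise ValueError(f"daily series does not cover {missing[0].date()}")
    return float(vals.sum())


def concat_actual_forecast(
    actual,
    model: ForecastModel | None,
    cutover: date,
    horizon: date,
) -> pd.Series:
    """Daily means: measured values before ``cutover``, forecast after.

    Mirrors the lead-time protocol where the final weeks before harvest
    are supplied by the forecaster instead of the sensor; interior
    sensor gaps (outage days) are also filled by the model.
    """
    s = _series_lookup(actual).dropna()
    if s.empty:
        raise ValueError("no observed days in the actual series")
    full = pd.date_range(s.index.min(), max(pd.Timestamp(horizon), s.index.max()), freq="D")
    out = s.reindex(full)
    fill = (full >= pd.Timestamp(cutover)) | out.isna().to_numpy()
    if fill.any():
        if model is None:
            raise ValueError("forecast model required to cover dates past the cutover or sensor gaps")
        out[fill] = model.predict(full[fill])
    return out


def harvest_window(
    bloom: date,
    series=None,
    rule: IntegrationRule = IntegrationRule(),
    *,
    actual=None,
    model: ForecastModel | None = None,
    cutover: date | None = None,
    max_days: int = 400,
) -> tuple[date, date]:
    """Predict the (earliest, latest) harvest dates for one bloom.

    Either pass a complete daily ``series`` covering the window, or the
    ``actual``/``model``/``cutover`` triple to splice measured and
    forecast temperatures.  The earliest date is bloom + n_lo where
    n_lo is the smallest n whose inclusive cumulative sum reaches
    ``rule.lo``; the latest is bloom + n_hi, the largest n whose sum
    stays <= ``rule.hi``.
    """
    if series is None:
        if actual is None or cutover is None:
            raise ValueError("need either a spliced series or actual+model+cutover")
        horizon = bloom + timedelta(days=max_days)
        series = concat_actual_forecast(actual, model, cutover, horizon)
    s = _series_lookup(series)
    start = pd.Timestamp(bloom)
    if start not in s.index or pd.isna(s.loc[start]):
        raise ValueError(f"daily series does not cover the bloom date {bloom}")
    span = s.reindex(pd.date_range(start, s.index.max(), freq="D"))
    vals = span.to_numpy(dtype=float)
    gaps = np.flatnonzero(np.isnan(vals))
    if len(gaps):
        vals = vals[: gaps[0]]  # usable prefix only
    csum = np.cumsum(vals)
    reached = np.flatnonzero(csum >= rule.lo)
    if len(reached) == 0:
        raise ValueError(
            f"series exhausted before reaching {rule.lo} degree-days "
            f"(partial sum {csum[-1] if len(csum) else 0.0:.1f} over {len(vals)} days)"
        )
    n_lo = int(reached[0])
    within = np.flatnonzero(csum <= rule.hi)
    n_hi = int(within[-1]) if len(within) else n_lo
    n_hi = max(n_hi, n_lo)  # degenerate when one hot day overshoots both bounds
    return (bloom + timedelta(days=n_lo), bloom + timedelta(days=n_hi))


def predict_fruit_count(state: TrussState) -> int:
    """Fruits expected at harvest: tracks that set fruit and were retained."""
    return sum(1 for t in state.tracks if t.state in (FRUIT, COMPLETED))


def predict_truss(
    state: TrussState,
    series=None,
    rule: IntegrationRule = IntegrationRule(),
    *,
    anchor: str = "earliest_bloom",
    **window_kwargs,
) -> HarvestPrediction:
    """Harvest window + fruit count for one truss.

    The window is anchored at the truss's earliest bloom date by
    default (``anchor='earliest_bloom'``); ``'latest_bloom'`` anchors
    at the last flower instead.
    """
    blooms = sorted(t.bloom_date for t in state.tracks)
    if not blooms:
        raise ValueError(f"truss {state.plant}_{state.truss} has no tracks to predict from")
    bloom = blooms[0] if anchor == "earliest_bloom" else blooms[-1]
    earliest, latest = harvest_window(bloom, series, rule, **window_kwargs)
    return HarvestPrediction(
        plant=state.plant,
        truss=state.truss,
        earliest=earliest,
        latest=latest,
        fruit_count=predict_fruit_count(state),
        bloom_dates_used=tuple(blooms),
    )


def daily_harvest_schedule(
    predictions: Iterable[HarvestPrediction],
    attribution: str = "uniform",
) -> dict[date, float]:
    """Expected fruit count per calendar day across all trusses.

    Each truss's count is spread uniformly over its window by default;
    ``attribution='midpoint'`` assigns it all to the window midpoint.
    """
    out: dict[date, float] = {}
    for p in predictions:
        days = (p.latest - p.earliest).days + 1
        if attribution == "midpoint":
            out[p.midpoint] = out.get(p.midpoint, 0.0) + p.fruit_count
        else:
            per_day = p.fruit_count / days
            for i in range(days):
                d = p.earliest + timedelta(days=i)
                out[d] = out.get(d, 0.0) + per_day
    return dict(sorted(out.items()))


def evaluate_harvest(
    predicted: Mapping[tuple[int, int], date],
    recorded: Mapping[tuple[int, int], date],
    lead_weeks: int = 0,
) -> HarvestEval:
    """MAE in days between predicted and recorded harvest dates.

    Only trusses present in both maps are scored; raises if there are
    none.  ``lead_weeks`` labels which forecast lead time produced the
    predictions (0 = measured temperatures throughout).
    """
    shared = sorted(set(predicted) & set(recorded))
    if not shared:
        raise ValueError("no shared truss keys between predictions and records")
    per_truss = {
        key: float(abs((predicted[key] - recorded[key]).days)) for key in shared
    }
    return HarvestEval(
        per_truss_mae=per_truss,
        overall_mae=float(np.mean(list(per_truss.values()))),
        lead_weeks=lead_weeks,
    )


def predictions_to_csv(predictions: Iterable[HarvestPrediction], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plant": p.plant,
                "truss": p.truss,
                "earliest": p.earliest.isoformat(),
                "latest": p.latest.isoformat(),
                "fruit_count": p.fruit_count,
            }
            for p in predictions
        ]
    )
    df.to_csv(path, index=False)


def predictions_from_csv(path: str | Path) -> list[HarvestPrediction]:
    df = pd.read_csv(path)
    return [
        HarvestPrediction(
            plant=int(r.plant),
            truss=int(r.truss),
            earliest=pd.Timestamp(r.earliest).date(),
            latest=pd.Timestamp(r.latest).date(),
            fruit_count=int(r.fruit_count),
        )
        for r in df.itertuples()
    ]
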