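"""End-to-end orchestration: simulate -> track -> forecast -> predict -> evaluate.

This is the programmatic counterpart of the CLI: each function takes
and returns in-memory objects, so the same code path serves shell
users, the test suite, and reproducibility scripts.

The default synthetic experiment mirrors the study design the pipeline
was built for: one plant monitored truss by truss (seven trusses whose
first flowers open ~10 days apart in early autumn), a two-year
greenhouse temperature log for forecaster training, and harvest
records confirmed only on Mondays, Wednesdays and Fridays.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import pandas as pd

from trusscast.config import PipelineConfig, ScenarioSettings
from trusscast.harvest import (
    HarvestEval,
    HarvestPrediction,
    IntegrationRule,
    evaluate_harvest,
    harvest_window,
    predict_fruit_count,
)
from trusscast.synthetic import GroundTruth, TempScenario, TrussScenario, gen_temperature, gen_truss_stream
from trusscast.thermal import (
    DailySeries,
    ForecastModel,
    daily_average,
    fit_forecaster,
    forecast,
    mae,
)
from trusscast.tracking import TrackerConfig, TrussState, TrussTracker


def temp_scenario(s: ScenarioSettings, seed: int) -> TempScenario:
    return TempScenario(
        start=pd.Timestamp(s.temp_start).date(),
        end=pd.Timestamp(s.temp_end).date(),
        noise_sd=s.noise_sd,
        outlier_rate=s.outlier_rate,
        missing_span_rate=s.missing_span_rate,
        seed=seed,
    )


def truss_scenarios(s: ScenarioSettings, seed: int) -> list[TrussScenario]:
    """Seven trusses (by default) blooming ~10 days apart on one plant."""
    start = pd.Timestamp(s.bloom_start).date()
    out = []
    for k in range(s.n_trusses):
        first = start + timedelta(days=10 * k)
        out.append(
            TrussScenario(
                plant=1,
                truss=k + 1,
                n_flowers=s.n_flowers,
                bloom_dates=tuple(first + timedelta(days=3 * i) for i in range(s.n_flowers)),
                jitter_sd_px=s.jitter_sd_px,
                drop_prob=s.drop_prob,
                nonfruit_prob=s.nonfruit_prob,
                frames_per_day=s.frames_per_day,
                seed=seed + 1000 + k,
            )
        )
    return out


@dataclass
class Simulation:
    """Everything one synthetic run produces."""

    records: pd.DataFrame  # raw 5-min temperature log
    true_daily: DailySeries
    streams: dict[tuple[int, int], list]
    truths: dict[tuple[int, int], GroundTruth]


def simulate(config: PipelineConfig, seed: int | None = None) -> Simulation:
    seed = config.seed if seed is None else seed
    records, true_daily = gen_temperature(temp_scenario(config.scenario, seed))
    streams: dict[tuple[int, int], list] = {}
    truths: dict[tuple[int, int], GroundTruth] = {}
    for sc in truss_scenarios(config.scenario, seed):
        frames, gt = gen_truss_stream(sc, true_daily, config.rule)
        streams[(sc.plant, sc.truss)] = frames
        truths[(sc.plant, sc.truss)] = gt
    return Simulation(records, true_daily, streams, truths)


def track_streams(
    streams: Mapping[tuple[int, int], Sequence],
    config: TrackerConfig | None = None,
) -> dict[tuple[int, int], TrussState]:
    """Run the centroid tracker over every truss's frame sequence."""
    out: dict[tuple[int, int], TrussState] = {}
    for (plant, truss), frames in streams.items():
        tracker = TrussTracker(plant, truss, config)
        for t, boxes in frames:
            tracker.update(boxes, t)
        out[(plant, truss)] = tracker.state
    return out


def train_forecaster(
    records: pd.DataFrame,
    train_end: date,
    config: PipelineConfig,
) -> tuple[ForecastModel, DailySeries]:
    """Daily-average the raw log and fit the forecaster on data up to
    ``train_end`` (inclusive); returns the model and the full daily series."""
    daily = daily_average(records, config.qc)
    cut = daily.index <= pd.Timestamp(train_end)
    train = DailySeries(daily.index[cut], daily.values[cut], daily.observed[cut])
    model = fit_forecaster(train, config.forecaster)
    return model, daily


def predict_trusses(
    states: Mapping[tuple[int, int], TrussState],
    actual: DailySeries,
    model: ForecastModel | None,
    cutovers: Mapping[tuple[int, int], date] | date | None,
    rule: IntegrationRule,
) -> list[HarvestPrediction]:
    """Per-truss harvest window + fruit count, splicing measured and
    forecast temperatures at each truss's cutover date.

    ``cutovers`` may be a single date, a per-truss map, or None (use
    measured temperatures throughout - the lead-0 protocol).
    """
    preds = []
    actual_s = actual.to_series().dropna()
    for key, state in sorted(states.items()):
        blooms = sorted(t.bloom_date for t in state.tracks)
        if not blooms:
            continue
        bloom = blooms[0]
        cut = cutovers.get(key) if isinstance(cutovers, Mapping) else cutovers
        if cut is None and model is not None:
            # measured temperatures throughout, model only fills gaps / tail
            cut = (actual_s.index.max() + pd.Timedelta(days=1)).date()
        if cut is None:
            earliest, latest = harvest_window(bloom, actual_s, rule)
        else:
            earliest, latest = harvest_window(
                bloom, None, rule, actual=actual_s, model=model, cutover=cut
            )
        preds.append(
            HarvestPrediction(
                plant=key[0],
                truss=key[1],
                earliest=earliest,
                latest=latest,
                fruit_count=predict_fruit_count(state),
                bloom_dates_used=tuple(blooms),
            )
        )
    return preds


def lead_time_eval(
    states: Mapping[tuple[int, int], TrussState],
    actual: DailySeries,
    model: ForecastModel | None,
    recorded: Mapping[tuple[int, int], date],
    lead_weeks: int,
    rule: IntegrationRule,
    representative: str = "midpoint",
) -> tuple[HarvestEval, list[HarvestPrediction]]:
    """One lead-time experiment: the last ``lead_weeks`` weeks of
    temperatures before each truss's recorded harvest are supplied by
    the forecaster instead of the sensor, and the predicted dates are
    scored against the records."""
    if lead_weeks == 0:
        cutovers: Mapping | None = None
    else:
        cutovers = {k: d - timedelta(weeks=lead_weeks) for k, d in recorded.items()}
    preds = predict_trusses(states, actual, model, cutovers, rule)
    pred_dates = {(p.plant, p.truss): p.representative(representative) for p in preds}
    return evaluate_harvest(pred_dates, recorded, lead_weeks), preds


def forecast_skill(
    model: ForecastModel, actual: DailySeries, start: date, end: date
) -> float:
    """Out-of-sample forecast MAE (deg C) over [start, end]."""
    span = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    actual_s = actual.to_series().reindex(span).dropna()
    pred = forecast(model, actual_s.index)
    return mae(pred, actual_s)
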