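"""Ground-truthed synthetic greenhouse data.

Stands in for the cameras and sensors: a seasonal greenhouse
temperature log at 5-min cadence (with injected outliers and outage
spans), and per-truss detection streams in which flowers bloom, set
fruit, grow by accumulated degree-days toward the ~3 cm monitoring
endpoint, occasionally drop or fail to set, jitter from frame to
frame, and suffer camera shifts.  Every stream ships with its ground
truth (true tracks, event dates, harvest windows), so tracking and
harvest prediction can be validated end to end without hardware.

Temperature defaults emulate a heated greenhouse in a temperate
climate: ~17 degree C annual mean, ~7 degrees seasonal amplitude
peaking in late July, a ~4-degree diurnal cycle, and day-to-day
weather noise of 2 degrees C - which leaves a well-fit seasonal
forecaster with a mean absolute error around 1.6 degrees C, the skill
of a good greenhouse sensor model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from trusscast.boxes import Box, CLS_FLOWER, CLS_FRUIT
from trusscast.harvest import IntegrationRule, harvest_window
from trusscast.thermal import DailySeries

__all__ = [
    "TempScenario",
    "TrussScenario",
    "GroundTruth",
    "gen_temperature",
    "gen_truss_stream",
    "render_frame",
    "detect_blobs",
    "snap_to_harvest_days",
]

YEAR_DAYS = 365.25


@dataclass(frozen=True)
class TempScenario:
    """Parameters of the synthetic greenhouse temperature series."""

    start: date
    end: date
    base_c: float = 17.0
    amp_c: float = 7.0
    phase_day: int = 205  # day-of-year of the seasonal peak (late July)
    diurnal_amp_c: float = 4.0
    noise_sd: float = 2.0  # day-to-day weather noise, deg C
    record_noise_sd: float = 0.3  # per-record sensor noise, deg C
    outlier_rate: float = 0.0  # per-record probability of a QC-failing spike
    missing_span_rate: float = 0.0  # expected outage spans per 30 days
    cadence_min: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} before start {self.start}")
        for name in ("outlier_rate", "missing_span_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name == "outlier_rate":
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_temperature(sc: TempScenario) -> tuple[pd.DataFrame, DailySeries]:
    """Generate raw 5-min records and the true daily-mean series.

    The true daily mean is seasonal signal + daily weather noise; raw
    records add a zero-mean diurnal cycle and per-record sensor noise,
    then outliers and outage spans are injected.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(sc.seed)
    days = pd.date_range(sc.start, sc.end, freq="D")
    doy = days.dayofyear.to_numpy(dtype=float)
    seasonal = sc.base_c + sc.amp_c * np.cos(2 * np.pi * (doy - sc.phase_day) / YEAR_DAYS)
    day_noise = rng.normal(0.0, sc.noise_sd, len(days)) if sc.noise_sd > 0 else np.zeros(len(days))
    true_means = seasonal + day_noise
    true_daily = DailySeries(days, true_means, np.ones(len(days), dtype=bool))

    per_day = (24 * 60) // sc.cadence_min
    minutes = np.arange(per_day) * sc.cadence_min
    # diurnal cosine peaking at 14:00; sums to exactly zero over a full day
    diurnal = sc.diurnal_amp_c * np.cos(2 * np.pi * (minutes - 14 * 60) / (24 * 60.0))

    stamps = []
    values = []
    for i, d in enumerate(days):
        vals = true_means[i] + diurnal
        if sc.record_noise_sd > 0:
            vals = vals + rng.normal(0.0, sc.record_noise_sd, per_day)
        stamps.append(d.to_numpy() + minutes.astype("timedelta64[m]"))
        values.append(vals)
    ts = np.concatenate(stamps)
    temp = np.concatenate(values)

    if sc.outlier_rate > 0:
        hit = rng.random(len(temp)) < sc.outlier_rate
        n_hit = int(hit.sum())
        # spikes far outside the physical range so QC removes them all
        spikes = rng.uniform(70.0, 120.0, n_hit) * rng.choice([-1.0, 1.0], n_hit)
        temp = temp.copy()
        temp[hit] = spikes

    keep = np.ones(len(temp), dtype=bool)
    if sc.missing_span_rate > 0:
        n_days = len(days)
        n_spans = rng.poisson(sc.missing_span_rate * n_days / 30.0)
        for _ in range(n_spans):
            start_idx = rng.integers(0, len(temp))
            span_records = int(rng.uniform(2, 36) * 60 / sc.cadence_min)  # 2-36 h outage
            keep[start_idx : start_idx + span_records] = False

    df = pd.DataFrame({"timestamp": pd.DatetimeIndex(ts[keep]), "temp_c": temp[keep]})
    return df, true_daily


@dataclass(frozen=True)
class TrussScenario:
    """Parameters of one synthetic truss's detection stream."""

    plant: int = 1
    truss: int = 1
    n_flowers: int = 4
    bloom_dates: tuple[date, ...] = ()
    spacing_px: float = 300.0
    jitter_sd_px: float = 2.0
    frames_per_day: int = 1
    fruit_set_days: int = 7  # days from anthesis to visible fruit set
    drop_prob: float = 0.0
    nonfruit_prob: float = 0.0
    shift_events: tuple[tuple[date, float, float], ...] = ()
    frame_width_px: float = 1600.0
    frame_height_px: float = 1200.0
    mm_per_px: float = 0.15
    flower_diameter_cm: float = 2.5
    fruit_max_diameter_cm: float = 6.0
    # degree-day fraction of the harvest threshold at which diameter = 3 cm
    size_endpoint_frac: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_prob", "nonfruit_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bloom_dates and len(self.bloom_dates) != self.n_flowers:
            raise ValueError("bloom_dates length must equal n_flowers")
        if self.spacing_px <= 4 * self.jitter_sd_px:
            raise ValueError("spacing_px must exceed 4 x jitter_sd_px for identifiability")


@dataclass
class TrueTrack:
    """Generator-side truth for one flower."""

    tid: str
    bloom_date: date
    outcome: str  # fruited | dropped | non_fruiting
    fruit_date: date | None = None
    drop_date: date | None = None
    end_date: date | None = None  # last day the object is visible


@dataclass
class GroundTruth:
    """Everything the generator knows about one truss's stream."""

    plant: int
    truss: int
    tracks: list[TrueTrack]
    harvest_earliest: date
    harvest_latest: date
    fruit_count: int
    box_track: dict[tuple[datetime, int], str] = field(default_factory=dict)

    @property
    def bloom_dates(self) -> dict[str, date]:
        return {t.tid: t.bloom_date for t in self.tracks}

    def recorded_harvest(self, mwf: bool = True) -> date:
        """A plausible manual harvest record: the window midpoint,
        optionally snapped to the Mon/Wed/Fri confirmation schedule."""
        mid = self.harvest_earliest + timedelta(
            days=(self.harvest_latest - self.harvest_earliest).days // 2
        )
        return snap_to_harvest_days(mid) if mwf else mid


def snap_to_harvest_days(d: date) -> date:
    """Nearest Monday/Wednesday/Friday (harvest-confirmation days)."""
    candidates = [d + timedelta(days=k) for k in range(-3, 4) if (d + timedelta(days=k)).weekday() in (0, 2, 4)]
    return min(candidates, key=lambda x: (abs((x - d).days), x.toordinal()))


def _diameter_cm(sc: TrussScenario, degree_days: float, rule: IntegrationRule) -> float:
    """Logistic fruit growth in accumulated thermal time."""
    f_mid = sc.size_endpoint_frac * rule.lo
    k = 8.0 / rule.lo  # growth steepness; ~full size near the harvest threshold
    return sc.fruit_max_diameter_cm / (1.0 + np.exp(-k * (degree_days - f_mid)))


def gen_truss_stream(
    sc: TrussScenario,
    true_daily: DailySeries,
    rule: IntegrationRule = IntegrationRule(),
) -> tuple[list[tuple[datetime, list[Box]]], GroundTruth]:
    """Generate a per-frame detection stream and its ground truth.

    Flowers appear on their bloom dates at fixed, well-separated
    anchor positions; each sets fruit after ``fruit_set_days`` (unless
    non-fruiting), grows along the degree-day logistic, and disappears
    early if dropped.  Positions get per-frame Gaussian jitter plus
    cumulative camera-shift translations.  The ground-truth harvest
    window comes from the true temperatures and the integration rule,
    anchored at the earliest bloom.
    """
    rng = np.random.default_rng(sc.seed)
    blooms = list(sc.bloom_dates) if sc.bloom_dates else [
        true_daily.index[0].date() + timedelta(days=int(3 * i)) for i in range(sc.n_flowers)
    ]
    order = sorted(range(len(blooms)), key=lambda i: (blooms[i], i))

    # anchor positions on a jittered grid with guaranteed spacing
    n = len(blooms)
    cols = int(np.ceil(np.sqrt(n)))
    anchors = []
    for idx in range(n):
        r, c = divmod(idx, cols)
        x = 200.0 + c * sc.spacing_px
        y = 200.0 + r * sc.spacing_px
        if x + 120 > sc.frame_width_px or y + 120 > sc.frame_height_px:
            raise ValueError("scenario overcrowded: anchors exceed the frame")
        anchors.append((x, y))

    tday = true_daily.to_series()
    temps = {ts.date(): float(v) for ts, v in tday.items()}

    tracks: list[TrueTrack] = []
    for pos, idx in enumerate(order, start=1):
        tid = f"{sc.plant}_{sc.truss}_{pos}"
        bloom = blooms[idx]
        u = rng.random()
        if u < sc.nonfruit_prob:
            tr = TrueTrack(tid, bloom, "non_fruiting",
                           end_date=bloom + timedelta(days=5))
        else:
            fruit_d = bloom + timedelta(days=sc.fruit_set_days)
            if rng.random() < sc.drop_prob:
                drop_d = fruit_d + timedelta(days=int(rng.integers(5, 15)))
                tr = TrueTrack(tid, bloom, "dropped", fruit_date=fruit_d,
                               drop_date=drop_d, end_date=drop_d)
            else:
                tr = TrueTrack(tid, bloom, "fruited", fruit_date=fruit_d)
        tracks.append(tr)
    anchor_by_tid = {tr.tid: anchors[idx] for tr, idx in zip(tracks, order)}

    first_bloom = min(t.bloom_date for t in tracks)
    e, l = harvest_window(first_bloom, true_daily, rule)
    fruit_count = sum(1 for t in tracks if t.outcome == "fruited")

    # stream runs until every surviving fruit passes 3 cm (endpoint of
    # monitoring), capped by the temperature series
    def dd(bloom: date, day: date) -> float:
        total, cur = 0.0, bloom
        while cur <= day:
            total += temps.get(cur, 0.0)
            cur += timedelta(days=1)
        return total

    last_day = true_daily.index[-1].date()
    end_day = first_bloom
    for tr in tracks:
        if tr.outcome == "fruited":
            d = tr.fruit_date
            while d <= last_day and _diameter_cm(sc, dd(tr.fruit_date, d), rule) < 3.2:
                d += timedelta(days=1)
            end_day = max(end_day, min(d, last_day))
        else:
            end_day = max(end_day, tr.end_date or tr.bloom_date)
    end_day = min(end_day + timedelta(days=1), last_day)
    # surviving fruits stay visible until monitoring of the truss stops
    for tr in tracks:
        if tr.outcome == "fruited":
            tr.end_date = end_day

    shift_events = sorted(sc.shift_events)
    frames: list[tuple[datetime, list[Box]]] = []
    gt = GroundTruth(sc.plant, sc.truss, tracks, e, l, fruit_count)

    day = first_bloom
    while day <= end_day:
        shift = np.array([0.0, 0.0])
        for ev_date, dx, dy in shift_events:
            if day >= ev_date:
                shift += (dx, dy)
        for k in range(sc.frames_per_day):
            t = datetime.combine(day, time(9, 0)) + timedelta(
                minutes=int(k * (8 * 60 / max(sc.frames_per_day, 1)))
            )
            boxes: list[Box] = []
            for tr in tracks:
                if day < tr.bloom_date or (tr.end_date and day > tr.end_date):
                    continue
                ax, ay = anchor_by_tid[tr.tid]
                jx, jy = rng.normal(0.0, sc.jitter_sd_px, 2) if sc.jitter_sd_px > 0 else (0.0, 0.0)
                cx, cy = ax + shift[0] + jx, ay + shift[1] + jy
                if tr.fruit_date is not None and day >= tr.fruit_date:
                    diam = _diameter_cm(sc, dd(tr.fruit_date, day), rule)
                    cls = CLS_FRUIT
                else:
                    diam = sc.flower_diameter_cm
                    cls = CLS_FLOWER
                size_px = diam * 10.0 / sc.mm_per_px
                boxes.append(Box(cx, cy, size_px, size_px, cls=cls, score=1.0, t=t))
                gt.box_track[(t, len(boxes) - 1)] = tr.tid
            frames.append((t, boxes))
        day += timedelta(days=1)
    return frames, gt


def render_frame(
    boxes: Sequence[Box],
    size: tuple[int, int] = (300, 400),
) -> np.ndarray:
    """Render boxes as colored disks on a dark background (toy imagery).

    Flowers are yellow disks, immature fruits green, on a (H, W, 3)
    uint8 canvas.  Warns when two disks overlap enough to merge.
    """
    h, w = size
    img = np.full((h, w, 3), 20, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = [(b.cx, b.cy, min(b.w, b.h) / 2.0) for b in boxes]
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            xi, yi, ri = centers[i]
            xj, yj, rj = centers[j]
            if np.hypot(xi - xj, yi - yj) < 0.8 * (ri + rj):
                warnings.warn(f"disks {i} and {j} overlap; blobs may merge")
    for b, (cx, cy, r) in zip(boxes, centers):
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        color = (235, 210, 40) if b.cls == CLS_FLOWER else (60, 200, 70)
        img[mask] = color
    return img


def detect_blobs(image: np.ndarray) -> list[Box]:
    """Recover boxes from a rendered frame by color thresholding.

    Connected components of the yellow mask become flower boxes, of
    the green mask fruit boxes; each gets score 1.0.
    """
    from scipy import ndimage

    img = image.astype(np.int16)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    masks = {
        CLS_FLOWER: (r > 150) & (g > 150) & (b < 120),
        CLS_FRUIT: (g > 150) & (r < 150),
    }
    out: list[Box] = []
    for cls, mask in masks.items():
        labels, n = ndimage.label(mask)
        for sl in ndimage.find_objects(labels):
            if sl is None:
                continue
            y0, y1 = sl[0].start, sl[0].stop
            x0, x1 = sl[1].start, sl[1].stop
            out.append(
                Box((x0 + x1) / 2.0, (y0 + y1) / 2.0, float(x1 - x0), float(y1 - y0),
                    cls=cls, score=1.0)
            )
    return out
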