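"""Flower-to-fruit tracking by centroid matching with hierarchical IDs.

Each detected bloom gets a tracking ID ``plant_truss_position`` at
first appearance; across frames, boxes are re-associated to tracks by
Euclidean distance between box centers (greedy nearest within a gate).
A flower track transitions to fruit once it is matched to
immature-fruit detections for a configurable number of consecutive
frames, to non-fruiting if it vanishes for too long, and a fruit to
dropped likewise; a truss is complete when all its fruits reach the
monitoring endpoint (~3 cm estimated diameter) and no flowers remain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

import numpy as np

from trusscast.boxes import Box, CLS_FLOWER, CLS_FRUIT, InvalidBoxError

FLOWER = "flower"
FRUIT = "fruit"
COMPLETED = "completed"
DROPPED = "dropped"
NON_FRUITING = "non_fruiting"

ACTIVE_STATES = (FLOWER, FRUIT)
# completed fruits remain visible until truss monitoring stops, so they
# keep claiming their boxes; dropped / non-fruiting tracks do not
MATCHABLE_STATES = (FLOWER, FRUIT, COMPLETED)


@dataclass(frozen=True, order=True)
class TrackingID:
    """Hierarchical identifier ``plant_truss_position``."""

    plant: int
    truss: int
    position: int

    def __post_init__(self) -> None:
        if min(self.plant, self.truss, self.position) < 1:
            raise ValueError("plant, truss and position must be positive")

    def __str__(self) -> str:
        return f"{self.plant}_{self.truss}_{self.position}"

    @classmethod
    def parse(cls, s: str) -> "TrackingID":
        p, t, pos = (int(x) for x in s.split("_"))
        return cls(p, t, pos)


@dataclass
class TrackerConfig:
    """Tunable tracker behavior.

    gate_px : float
        Maximum center distance for re-association.  Defaults to 25%
        of ``frame_width_px``.
    fruit_confirm_frames : int
        Consecutive fruit-class matches before a flower is declared a
        fruit (single-frame misclassification tolerance).
    nonfruit_horizon_days / drop_horizon_days : float
        How long a flower / fruit may go unseen before being declared
        non-fruiting / dropped.
    mm_per_px : float
        Image scale for diameter estimation.  The default corresponds
        to a ~17.5 cm camera-to-truss distance with a 65-degree FOV at
        1600 px width; true scale varies per install.
    compensate_shift : bool
        Estimate and remove a global frame translation (median
        displacement of mutual-nearest pairs) before matching, to
        absorb camera shifts from agricultural work.
    """

    frame_width_px: float = 1600.0
    gate_px: float | None = None
    fruit_confirm_frames: int = 3
    nonfruit_horizon_days: float = 14.0
    drop_horizon_days: float = 3.0
    mm_per_px: float = 0.15
    min_diameter_cm: float = 3.0
    compensate_shift: bool = True

    @property
    def gate(self) -> float:
        return self.gate_px if self.gate_px is not None else 0.25 * self.frame_width_px


@dataclass
class Track:
    """One flower/fruit lifeline with dated box history."""

    id: TrackingID
    state: str
    bloom_date: date
    history: list[tuple[datetime, Box]]
    fruit_date: date | None = None
    _fruit_streak: int = 0
    _streak_start: date | None = None

    @property
    def last_seen(self) -> datetime:
        return self.history[-1][0]

    @property
    def last_box(self) -> Box:
        return self.history[-1][1]

    def diameter_cm(self, mm_per_px: float) -> float:
        return estimate_diameter(self.last_box, mm_per_px)

    def observe(self, t: datetime, box: Box, confirm_frames: int) -> None:
        if t > self.last_seen:
            self.history.append((t, box))
        if self.state == FLOWER:
            if box.cls == CLS_FRUIT:
                if self._fruit_streak == 0:
                    self._streak_start = t.date()
                self._fruit_streak += 1
                if self._fruit_streak >= confirm_frames:
                    self.state = FRUIT
                    self.fruit_date = self._streak_start
            else:
                self._fruit_streak = 0
                self._streak_start = None


def estimate_diameter(b: Box, mm_per_px: float) -> float:
    """Estimated object diameter in cm from a pixel box and image scale."""
    if mm_per_px <= 0:
        raise ValueError(f"mm_per_px must be positive, got {mm_per_px}")
    if b.w <= 0 or b.h <= 0:
        raise InvalidBoxError("cannot size a box with non-positive extents")
    return mm_per_px * 0.5 * (b.w + b.h) / 10.0


@dataclass
class TrussState:
    """All tracks of one monitored truss."""

    plant: int
    truss: int
    tracks: list[Track] = field(default_factory=list)
    complete: bool = False
    last_frame_t: datetime | None = None

    def track(self, tid: TrackingID | str) -> Track:
        tid = TrackingID.parse(tid) if isinstance(tid, str) else tid
        for tr in self.tracks:
            if tr.id == tid:
                return tr
        raise KeyError(str(tid))

    @property
    def next_position(self) -> int:
        return max((t.id.position for t in self.tracks), default=0) + 1

    def active_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.state in ACTIVE_STATES]

    def matchable_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.state in MATCHABLE_STATES]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "plant": self.plant,
                "truss": self.truss,
                "complete": self.complete,
                "tracks": [
                    {
                        "id": str(t.id),
                        "state": t.state,
                        "bloom_date": t.bloom_date.isoformat(),
                        "fruit_date": t.fruit_date.isoformat() if t.fruit_date else None,
                        "last_seen": t.last_seen.isoformat(),
                        "last_box": {
                            "cls": t.last_box.cls,
                            "cx": t.last_box.cx,
                            "cy": t.last_box.cy,
                            "w": t.last_box.w,
                            "h": t.last_box.h,
                        },
                        "n_observations": len(t.history),
                    }
                    for t in self.tracks
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _estimate_shift(tracks: Sequence[Track], boxes: Sequence[Box]) -> tuple[float, float]:
    """Median displacement of mutual-nearest track/box pairs."""
    if not tracks or not boxes:
        return (0.0, 0.0)
    tc = np.array([t.last_box.center for t in tracks])
    bc = np.array([b.center for b in boxes])
    d = np.linalg.norm(tc[:, None, :] - bc[None, :, :], axis=2)
    nb = d.argmin(axis=1)  # nearest box per track
    nt = d.argmin(axis=0)  # nearest track per box
    disp = [bc[nb[i]] - tc[i] for i in range(len(tracks)) if nt[nb[i]] == i]
    if not disp:
        return (0.0, 0.0)
    med = np.median(np.array(disp), axis=0)
    return (float(med[0]), float(med[1]))


def assign_ids(
    state: TrussState,
    frame: Sequence[Box],
    t: datetime,
    config: TrackerConfig | None = None,
) -> dict[str, Box]:
    """Associate current-frame boxes with existing tracks, in place.

    Active tracks claim their nearest box within the distance gate,
    greedily by increasing distance (ties by lower track ID); every
    unclaimed box spawns a new track with the next position number.
    Returns the mapping old-ID -> matched box for the claimed pairs.

    Raises if ``t`` precedes the previous frame.
    """
    config = config or TrackerConfig()
    if state.last_frame_t is not None and t < state.last_frame_t:
        raise ValueError(
            f"frame at {t} precedes previous frame {state.last_frame_t}; "
            "frames must arrive in time order"
        )
    boxes = list(frame)
    active = state.matchable_tracks()

    if config.compensate_shift and active and boxes:
        dx, dy = _estimate_shift(active, boxes)
        shifted = [
            Box(b.cx - dx, b.cy - dy, b.w, b.h, cls=b.cls, score=b.score, t=b.t)
            for b in boxes
        ]
    else:
        shifted = boxes

    # greedy matching by increasing center distance within the gate
    pairs: list[tuple[float, TrackingID, int, int]] = []
    for i, tr in enumerate(active):
        cx, cy = tr.last_box.center
        for j, b in enumerate(shifted):
            dist = float(np.hypot(b.cx - cx, b.cy - cy))
            if dist <= config.gate:
                pairs.append((dist, tr.id, i, j))
    pairs.sort(key=lambda p: (p[0], p[1]))
    used_t: set[int] = set()
    used_b: set[int] = set()
    mapping: dict[str, Box] = {}
    for dist, tid, i, j in pairs:
        if i in used_t or j in used_b:
            continue
        used_t.add(i)
        used_b.add(j)
        active[i].observe(t, boxes[j], config.fruit_confirm_frames)
        mapping[str(tid)] = boxes[j]

    for j, b in enumerate(boxes):
        if j in used_b:
            continue
        tid = TrackingID(state.plant, state.truss, state.next_position)
        state.tracks.append(
            Track(
                id=tid,
                state=FLOWER if b.cls == CLS_FLOWER else FRUIT,
                bloom_date=t.date(),
                fruit_date=t.date() if b.cls == CLS_FRUIT else None,
                history=[(t, b)],
            )
        )
    state.last_frame_t = t
    _assert_unique_ids(state)
    return mapping


def _assert_unique_ids(state: TrussState) -> None:
    ids = [t.id for t in state.tracks]
    if len(ids) != len(set(ids)):
        raise AssertionError(f"duplicate tracking IDs in truss {state.plant}_{state.truss}")


def update_states(state: TrussState, t: datetime, config: TrackerConfig | None = None) -> TrussState:
    """Apply the unseen-horizon rules as of time ``t``.

    A flower unseen past the non-fruiting horizon becomes non-fruiting;
    a fruit unseen past the drop horizon becomes dropped.  (The
    flower-to-fruit transition itself happens during assignment, when
    fruit-class matches accumulate.)
    """
    config = config or TrackerConfig()
    for tr in state.tracks:
        unseen_days = (t - tr.last_seen).total_seconds() / 86400.0
        if tr.state == FLOWER and unseen_days > config.nonfruit_horizon_days:
            tr.state = NON_FRUITING
        elif tr.state == FRUIT and unseen_days > config.drop_horizon_days:
            tr.state = DROPPED
    return state


def truss_complete(
    state: TrussState,
    min_diameter_cm: float = 3.0,
    mm_per_px: float = 0.15,
) -> bool:
    """True when every fruit reached the size endpoint and no flowers remain."""
    if not state.tracks:
        warnings.warn(f"truss {state.plant}_{state.truss} has no tracks")
        return False
    if any(t.state == FLOWER for t in state.tracks):
        return False
    fruiting = [t for t in state.tracks if t.state in (FRUIT, COMPLETED)]
    if not fruiting:
        return False
    return all(
        t.state == COMPLETED or t.diameter_cm(mm_per_px) >= min_diameter_cm
        for t in fruiting
    )


def bloom_events(state: TrussState) -> list[tuple[TrackingID, date]]:
    """Anthesis events: each track's first detection date, in ID order."""
    return [(t.id, t.bloom_date) for t in sorted(state.tracks, key=lambda t: t.id)]


class TrussTracker:
    """Stateful per-truss tracker: feed frames, read off the truss state."""

    def __init__(self, plant: int, truss: int, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.state = TrussState(plant=plant, truss=truss)

    def update(self, frame: Sequence[Box], t: datetime) -> dict[str, Box]:
        mapping = assign_ids(self.state, frame, t, self.config)
        update_states(self.state, t, self.config)
        if not self.state.complete and truss_complete(
            self.state, self.config.min_diameter_cm, self.config.mm_per_px
        ):
            for tr in self.state.tracks:
                if tr.state == FRUIT:
                    tr.state = COMPLETED
            self.state.complete = True
        return mapping
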