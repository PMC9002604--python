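"""Readers and writers for the pipeline's on-disk formats.

Detection streams are JSON-Lines, one frame per line::

    {"timestamp": "2020-09-01T09:00:00", "plant": 1, "truss": 3,
     "boxes": [{"cls": "bloomed_flower", "cx": 200.0, "cy": 200.0,
                "w": 160.0, "h": 160.0, "score": 0.97}]}

Temperature logs are CSV with columns ``timestamp, temp_c``; harvest
records CSV with ``plant, truss, harvest_date``.  Ground truth and
reports are JSON.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Iterable

import pandas as pd

from trusscast.boxes import Box
from trusscast.synthetic import GroundTruth, TrueTrack

Frames = list[tuple[datetime, list[Box]]]


def write_stream(frames: Frames, plant: int, truss: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, boxes in frames:
            fh.write(
                json.dumps(
                    {
                        "timestamp": t.isoformat(),
                        "plant": plant,
                        "truss": truss,
                        "boxes": [
                            {"cls": b.cls, "cx": b.cx, "cy": b.cy, "w": b.w, "h": b.h,
                             **({"score": b.score} if b.score is not None else {})}
                            for b in boxes
                        ],
                    }
                )
                + "\n"
            )


def read_streams(paths: Iterable[str | Path]) -> dict[tuple[int, int], Frames]:
    """Read one or more JSONL stream files, keyed by (plant, truss)."""
    out: dict[tuple[int, int], Frames] = {}
    for path in paths:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            for field in ("timestamp", "plant", "truss", "boxes"):
                if field not in rec:
                    raise ValueError(f"{path}:{lineno}: missing field {field!r}")
            t = datetime.fromisoformat(rec["timestamp"])
            boxes = [
                Box(b["cx"], b["cy"], b["w"], b["h"], cls=b["cls"], score=b.get("score"), t=t)
                for b in rec["boxes"]
            ]
            key = (int(rec["plant"]), int(rec["truss"]))
            out.setdefault(key, []).append((t, boxes))
    for frames in out.values():
        frames.sort(key=lambda f: f[0])
    return out


def write_ground_truth(gts: Iterable[GroundTruth], path: str | Path) -> None:
    payload = [
        {
            "plant": g.plant,
            "truss": g.truss,
            "harvest_earliest": g.harvest_earliest.isoformat(),
            "harvest_latest": g.harvest_latest.isoformat(),
            "fruit_count": g.fruit_count,
            "tracks": [
                {
                    "id": t.tid,
                    "bloom_date": t.bloom_date.isoformat(),
                    "outcome": t.outcome,
                    "fruit_date": t.fruit_date.isoformat() if t.fruit_date else None,
                    "drop_date": t.drop_date.isoformat() if t.drop_date else None,
                }
                for t in g.tracks
            ],
        }
        for g in gts
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    data = json.loads(Path(path).read_text())
    out = []
    for g in data:
        out.append(
            GroundTruth(
                plant=g["plant"],
                truss=g["truss"],
                tracks=[
                    TrueTrack(
                        tid=t["id"],
                        bloom_date=_d(t["bloom_date"]),
                        outcome=t["outcome"],
                        fruit_date=_d(t["fruit_date"]),
                        drop_date=_d(t["drop_date"]),
                    )
                    for t in g["tracks"]
                ],
                harvest_earliest=_d(g["harvest_earliest"]),
                harvest_latest=_d(g["harvest_latest"]),
                fruit_count=g["fruit_count"],
            )
        )
    return out


def _d(s):
    return None if s is None else datetime.fromisoformat(s).date()


def read_temperature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("timestamp", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: temperature CSV must have a {col!r} column")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_temperature_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_harvest_records(path: str | Path) -> dict[tuple[int, int], "datetime.date"]:
    df = pd.read_csv(path)
    for col in ("plant", "truss", "harvest_date"):
        if col not in df.columns:
            raise ValueError(f"{path}: harvest records CSV must have a {col!r} column")
    return {
        (int(r.plant), int(r.truss)): pd.Timestamp(r.harvest_date).date()
        for r in df.itertuples()
    }


def write_harvest_records(records: dict[tuple[int, int], "datetime.date"], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"plant": p, "truss": t, "harvest_date": d.isoformat()} for (p, t), d in sorted(records.items())]
    )
    df.to_csv(path, index=False)
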