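"""Axis-aligned detection boxes and the Darknet annotation format.

Boxes are center-format ``(cx, cy, w, h)`` — the convention of Darknet
annotation files — with the image origin at the top-left corner and y
increasing downward.  Coordinates may be pixels or normalized to [0, 1];
all geometry here is unit-agnostic as long as both boxes share a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

CLS_FLOWER = "bloomed_flower"
CLS_FRUIT = "immature_fruit"

#: Darknet class indices used in annotation text files.
CLASS_INDEX = {CLS_FLOWER: 0, CLS_FRUIT: 1}
CLASS_NAME = {v: k for k, v in CLASS_INDEX.items()}


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive extents or out-of-range scores."""


@dataclass(frozen=True)
class Box:
    """One detection: a center-format rectangle with class label.

    Parameters
    ----------
    cx, cy : float
        Center coordinates (pixels, or normalized to [0, 1]).
    w, h : float
        Width and height; must be strictly positive.
    cls : str
        Class label, one of ``bloomed_flower`` / ``immature_fruit``
        (other labels are accepted for generic use).
    score : float, optional
        Detection confidence in [0, 1]; required for AP ranking.
    t : datetime, optional
        Frame timestamp.
    """

    cx: float
    cy: float
    w: float
    h: float
    cls: str = CLS_FLOWER
    score: float | None = None
    t: datetime | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box extents must be positive, got w={self.w}, h={self.h}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise InvalidBoxError(f"score must be in [0, 1], got {self.score}")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    def corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )


def read_darknet(path: str | Path, *, cls_map: dict[int, str] | None = None) -> list[Box]:
    """Read a Darknet-style annotation file.

    One box per line: ``class_index cx cy w h`` with normalized
    coordinates, optionally followed by a confidence score.
    """
    cls_map = cls_map or CLASS_NAME
    boxes: list[Box] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        idx = int(parts[0])
        cx, cy, w, h = (float(p) for p in parts[1:5])
        score = float(parts[5]) if len(parts) == 6 else None
        boxes.append(Box(cx, cy, w, h, cls=cls_map.get(idx, str(idx)), score=score))
    return boxes


def write_darknet(boxes: Iterable[Box], path: str | Path) -> None:
    """Write boxes as Darknet annotation text (scores appended if present)."""
    lines = []
    for b in boxes:
        idx = CLASS_INDEX.get(b.cls)
        if idx is None:
            raise ValueError(f"no Darknet class index for label {b.cls!r}")
        fields = [str(idx)] + [f"{v:.6f}" for v in (b.cx, b.cy, b.w, b.h)]
        if b.score is not None:
            fields.append(f"{b.score:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def split_by_class(boxes: Sequence[Box]) -> dict[str, list[Box]]:
    out: dict[str, list[Box]] = {}
    for b in boxes:
        out.setdefault(b.cls, []).append(b)
    return out
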