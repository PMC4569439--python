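"""Grid-centroid construction of the four-mark point pattern.

A rectangular grid of ``box_size`` x ``box_size`` pixel boxes (default 8)
is anchored at the tight bounding box of the ROI. Within each box, each of
the four habitats contributes the center of mass of its pixels there (if
any), giving a planar point pattern with marks T1low / T1high / T2low /
T2high inside the rectangular observation window spanned by the ROI
bounding box.

Coordinate convention: 0-based pixel indices, a pixel's center is
(x=col, y=row), distances Euclidean in pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKS = ("T1low", "T1high", "T2low", "T2high")


@dataclass(frozen=True)
class GridSpec:
    box_size: int
    origin: tuple[int, int]  # (row, col) of ROI bounding box upper-left
    n_rows: int
    n_cols: int


@dataclass
class MultitypePointPattern:
    """Planar points with one of four categorical marks in a rectangle.

    ``window`` is (xmin, xmax, ymin, ymax); pixel (r, c) spans
    [c-0.5, c+0.5] x [r-0.5, r+0.5], so the window covers whole pixels.
    """

    points: np.ndarray          # (n, 2) float, columns (x, y)
    marks: np.ndarray           # (n,) str, values in MARKS
    window: tuple[float, float, float, float]
    metadata: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def window_sides(self) -> tuple[float, float]:
        xmin, xmax, ymin, ymax = self.window
        return (xmax - xmin, ymax - ymin)

    @property
    def window_area(self) -> float:
        w, h = self.window_sides
        return w * h

    def points_of(self, mark: str) -> np.ndarray:
        return self.points[self.marks == mark]

    def mark_counts(self) -> dict:
        return {m: int((self.marks == m).sum()) for m in MARKS}

    def subpattern(self, keep_marks) -> "MultitypePointPattern":
        keep = np.isin(self.marks, list(keep_marks))
        return MultitypePointPattern(points=self.points[keep],
                                     marks=self.marks[keep],
                                     window=self.window,
                                     metadata=dict(self.metadata))

    def to_csv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame({"x": self.points[:, 0], "y": self.points[:, 1],
                           "mark": self.marks})
        df.to_csv(path, index=False)
        if sidecar:
            meta = {"window": list(self.window), **self.metadata}
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "MultitypePointPattern":
        df = pd.read_csv(path)
        side = Path(str(path) + ".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        window = tuple(meta.pop("window", (df.x.min() - 0.5, df.x.max() + 0.5,
                                           df.y.min() - 0.5, df.y.max() + 0.5)))
        return cls(points=df[["x", "y"]].to_numpy(float),
                   marks=df["mark"].to_numpy(str), window=window,
                   metadata=meta)


def make_grid(mask: np.ndarray, box_size: int = 8) -> GridSpec:
    """Grid anchored at the tight ROI bounding box; edge boxes may clip."""
    if box_size < 2:
        raise ValueError("box_size must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows, cols = np.nonzero(mask)
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    h, w = r1 - r0 + 1, c1 - c0 + 1
    return GridSpec(box_size=box_size, origin=(r0, c0),
                    n_rows=-(-h // box_size), n_cols=-(-w // box_size))


def cell_centroid(pixel_coords) -> tuple[float, float] | None:
    """Mean pixel-center position as (x, y); None for an empty set."""
    coords = np.asarray(list(pixel_coords), dtype=float)
    if coords.size == 0:
        return None
    r, c = coords[:, 0].mean(), coords[:, 1].mean()
    return (float(c), float(r))


def build_point_pattern(habitats, grid: GridSpec) -> MultitypePointPattern:
    """Emit one centroid per (grid box, habitat) with pixels in that box."""
    mark_masks = habitats.as_dict()
    roi = habitats.roi()
    rows, cols = np.nonzero(roi)
    r0, c0 = grid.origin
    r1 = r0 + grid.n_rows * grid.box_size
    c1 = c0 + grid.n_cols * grid.box_size

    pts, mks = [], []
    for i in range(grid.n_rows):
        ra, rb = r0 + i * grid.box_size, min(r0 + (i + 1) * grid.box_size, r1)
        for j in range(grid.n_cols):
            ca, cb = c0 + j * grid.box_size, min(c0 + (j + 1) * grid.box_size, c1)
            for mark in MARKS:
                sub = mark_masks[mark][ra:rb, ca:cb]
                if not sub.any():
                    continue
                rr, cc = np.nonzero(sub)
                pts.append((cc.mean() + ca, rr.mean() + ra))
                mks.append(mark)

    window = (float(cols.min()) - 0.5, float(cols.max()) + 0.5,
              float(rows.min()) - 0.5, float(rows.max()) + 0.5)
    pattern = MultitypePointPattern(
        points=np.asarray(pts, dtype=float).reshape(-1, 2),
        marks=np.asarray(mks, dtype=object),
        window=window,
        metadata={"grid": {"box_size": grid.box_size,
                           "origin": list(grid.origin),
                           "n_rows": grid.n_rows, "n_cols": grid.n_cols},
                  "empty_marks": [m for m in MARKS
                                  if not mark_masks[m].any()]})
    return pattern
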