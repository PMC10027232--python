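"""Core containers: the point cloud and the breeding-plot map.

Coordinates are centimetres throughout the package; Z points up (the crop
growth direction). Per-point integer labels, when present, use 0 for
unassigned/ground and positive integers for plant instance or plot ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PointCloud:
    """N points in 3D, optionally with per-point intensity and integer labels.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of X, Y, Z in centimetres.
    intensity
        Optional ``(N,)`` float array.
    labels
        Optional ``(N,)`` integer array; 0 means unassigned/ground,
        positive values are instance ids.
    """

    points: np.ndarray
    intensity: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=np.float64).reshape(-1)
            if inten.shape[0] != pts.shape[0]:
                raise ValueError("intensity length does not match point count")
            self.intensity = inten
        if self.labels is not None:
            lab = np.asarray(self.labels).reshape(-1)
            if lab.shape[0] != pts.shape[0]:
                raise ValueError("labels length does not match point count")
            self.labels = lab.astype(np.int64)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud by boolean mask or integer index, labels kept aligned."""
        index = np.asarray(index)
        return PointCloud(
            points=self.points[index],
            intensity=None if self.intensity is None else self.intensity[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(points=self.points, intensity=self.intensity, labels=labels)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        """Apply the rigid map ``p -> R p + t`` to every point."""
        rotation = np.asarray(rotation, dtype=np.float64)
        translation = np.asarray(translation, dtype=np.float64).reshape(3)
        return PointCloud(
            points=self.points @ rotation.T + translation,
            intensity=self.intensity,
            labels=self.labels,
        )


@dataclass
class PlotCell:
    """One rectangular breeding plot: id, variety and half-open XY bounds."""

    plot_id: int
    variety: str
    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"plot {self.plot_id}: degenerate bounds")


@dataclass
class PlotMap:
    """Rectangular grid of breeding plots, each holding one variety.

    Cells must not overlap and plot ids must be unique. Membership uses
    half-open rectangles ``[xmin, xmax) x [ymin, ymax)`` so a point on a
    shared boundary belongs to exactly one plot.
    """

    cells: list[PlotCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.plot_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate plot ids in plot map")
        if any(i <= 0 for i in ids):
            raise ValueError("plot ids must be positive (0 is reserved)")
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1 :]:
                if (
                    a.xmin < b.xmax
                    and b.xmin < a.xmax
                    and a.ymin < b.ymax
                    and b.ymin < a.ymax
                ):
                    raise ValueError(
                        f"plots {a.plot_id} and {b.plot_id} overlap"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plot_id": c.plot_id,
                    "variety": c.variety,
                    "xmin": c.xmin,
                    "xmax": c.xmax,
                    "ymin": c.ymin,
                    "ymax": c.ymax,
                }
                for c in self.cells
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PlotMap":
        required = {"plot_id", "variety", "xmin", "xmax", "ymin", "ymax"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"plot map missing columns: {sorted(missing)}")
        cells = [
            PlotCell(
                plot_id=int(r.plot_id),
                variety=str(r.variety),
                xmin=float(r.xmin),
                xmax=float(r.xmax),
                ymin=float(r.ymin),
                ymax=float(r.ymax),
            )
            for r in frame.itertuples()
        ]
        return cls(cells=cells)
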