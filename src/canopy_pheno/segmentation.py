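"""Breeding-plot assignment and geometric plant instance segmentation.

Plants are separated by single-linkage Euclidean clustering on a voxel
occupancy graph: the ground-removed, leveled cloud is voxelized at the
connection distance and occupied voxels touching each other (26-neighbor
adjacency) belong to one instance. This deterministic geometric stage fills
the slot where a learned point-cloud segmentation network would run on real
canopies; the interface is instance-based so such a segmenter can be
dropped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from canopy_pheno.cloud import PlotMap, PointCloud
from canopy_pheno.preprocess import voxel_indices

DEFAULT_CELL_SIZE = 5.0  # cm
DEFAULT_MIN_POINTS = 50


@dataclass
class PlantInstance:
    """One segmented plant: id, member point indices and stem base."""

    instance_id: int
    point_indices: np.ndarray
    base_xy: tuple[float, float]

    @property
    def n_points(self) -> int:
        return len(self.point_indices)


def assign_plots(cloud: PointCloud, plots: PlotMap) -> PointCloud:
    """Label every point with the id of the plot rectangle containing it.

    Rectangles are half-open ``[xmin, xmax) x [ymin, ymax)``, so a point on
    a boundary shared by two plots belongs to the higher one. Points outside
    all plots get label 0.
    """
    labels = np.zeros(len(cloud), dtype=np.int64)
    for cell in plots.cells:
        inside = (
            (cloud.x >= cell.xmin)
            & (cloud.x < cell.xmax)
            & (cloud.y >= cell.ymin)
            & (cloud.y < cell.ymax)
        )
        labels[inside] = cell.plot_id
    return cloud.with_labels(labels)


def _stem_base(points: np.ndarray) -> tuple[float, float]:
    """XY median of the lowest Z-decile of a cluster."""
    z = points[:, 2]
    cutoff = np.quantile(z, 0.1)
    low = points[z <= cutoff]
    return float(np.median(low[:, 0])), float(np.median(low[:, 1]))


def segment_plants(
    cloud: PointCloud,
    cell_size: float = DEFAULT_CELL_SIZE,
    min_points: int = DEFAULT_MIN_POINTS,
    expected_spacing: float | None = None,
) -> list[PlantInstance]:
    """Cluster a ground-removed, leveled cloud into plant instances.

    Clusters with fewer than ``min_points`` points are discarded (with a
    count in a warning). When ``expected_spacing`` is given, a cluster whose
    XY span exceeds 1.8x that spacing triggers a touching-canopy warning —
    heavy leaf overlap is the known failure mode of geometric separation.
    Instances are ordered by stem base (Y, then X) and ids are 1-based.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if len(cloud) == 0:
        return []
    vox = voxel_indices(cloud.points, cell_size)
    uniq, inverse = np.unique(vox, axis=0, return_inverse=True)
    nv = len(uniq)

    # encode ijk -> single key for neighbor lookup
    span = uniq.max(axis=0) + 3
    def encode(ijk: np.ndarray) -> np.ndarray:
        return (ijk[:, 0] * span[1] + ijk[:, 1]) * span[2] + ijk[:, 2]

    keys = encode(uniq)
    order = np.argsort(keys)
    sorted_keys = keys[order]

    rows, cols = [], []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for off in offsets:
        nb = uniq + np.array(off)
        valid = (nb >= 0).all(axis=1)
        nb_keys = encode(np.clip(nb, 0, None))
        pos = np.searchsorted(sorted_keys, nb_keys)
        pos = np.clip(pos, 0, nv - 1)
        hit = valid & (sorted_keys[pos] == nb_keys)
        rows.append(np.flatnonzero(hit))
        cols.append(order[pos[hit]])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    graph = coo_matrix((np.ones(len(r)), (r, c)), shape=(nv, nv))
    _, vox_comp = connected_components(graph, directed=False)

    comp = vox_comp[inverse]  # per point
    instances: list[PlantInstance] = []
    n_discarded = 0
    for cid in np.unique(comp):
        idx = np.flatnonzero(comp == cid)
        if len(idx) < min_points:
            n_discarded += 1
            continue
        pts = cloud.points[idx]
        base = _stem_base(pts)
        if expected_spacing is not None:
            span_xy = pts[:, :2].max(axis=0) - pts[:, :2].min(axis=0)
            if span_xy.max() > 1.8 * expected_spacing:
                warnings.warn(
                    f"cluster at base {base} spans {span_xy.max():.1f} cm "
                    f"(> 1.8 x plant spacing): plants may be touching",
                    stacklevel=2,
                )
        instances.append(
            PlantInstance(instance_id=0, point_indices=idx, base_xy=base)
        )
    if n_discarded:
        warnings.warn(
            f"discarded {n_discarded} cluster(s) below min_points={min_points}",
            stacklevel=2,
        )
    instances.sort(key=lambda inst: (inst.base_xy[1], inst.base_xy[0]))
    for i, inst in enumerate(instances, start=1):
        inst.instance_id = i
    return instances


def instances_frame(instances: list[PlantInstance]) -> pd.DataFrame:
    """Instance summary table (instance_id, n_points, base_x, base_y)."""
    return pd.DataFrame(
        [
            {
                "instance_id": inst.instance_id,
                "n_points": inst.n_points,
                "base_x": inst.base_xy[0],
                "base_y": inst.base_xy[1],
            }
            for inst in instances
        ]
    )
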