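"""Statistical outlier removal and voxel-grid down-sampling.

The processing order in the pipeline is: statistical filtering first (to
delete stray sensor returns), voxel down-sampling second (to thin the cloud
while preserving plant shape, replacing every occupied voxel by the gravity
center of its points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from canopy_pheno.cloud import PointCloud

DEFAULT_SOR_K = 20
DEFAULT_SOR_STD = 2.0


@dataclass
class VoxelParams:
    """Cubic voxel grid anchored at the minimum corner of the cloud's
    bounding box; membership is half-open (a point on an upper face belongs
    to the higher-index voxel)."""

    edge_length: float  # cm

    def __post_init__(self) -> None:
        if self.edge_length <= 0:
            raise ValueError("voxel edge length must be positive")


@dataclass
class FilterReport:
    """Point counts before/after a filtering stage."""

    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValueError("filter cannot increase the point count")

    @property
    def retained_pct(self) -> float:
        return compression_summary(self)


def statistical_outlier_removal(
    cloud: PointCloud, k: int = DEFAULT_SOR_K, std_ratio: float = DEFAULT_SOR_STD
) -> tuple[PointCloud, FilterReport]:
    """Remove points whose mean k-nearest-neighbor distance is anomalous.

    A point is deleted when its mean distance to its ``k`` nearest
    neighbors exceeds (global mean + ``std_ratio`` * global standard
    deviation) of those per-point mean distances. Labels follow the points.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    n = len(cloud)
    if n <= k:
        raise ValueError(f"cloud has {n} points, need more than k={k}")
    tree = cKDTree(cloud.points)
    # k+1 because each point is its own nearest neighbor
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + std_ratio * mean_d.std()
    keep = mean_d <= threshold
    return cloud.select(keep), FilterReport(n_before=n, n_after=int(keep.sum()))


def voxel_indices(points: np.ndarray, edge: float) -> np.ndarray:
    """Integer voxel index of each point, grid anchored at the min corner."""
    origin = points.min(axis=0)
    return np.floor((points - origin) / edge).astype(np.int64)


def voxel_downsample(
    cloud: PointCloud, params: VoxelParams
) -> tuple[PointCloud, FilterReport]:
    """Replace each occupied voxel by the centroid of its points.

    The output has exactly one point per occupied voxel. When labels are
    present the output label is the majority label of the voxel's members,
    ties broken toward the smallest id. Output order follows the sorted
    integer voxel index, so results are deterministic.
    """
    n = len(cloud)
    if n == 0:
        return cloud, FilterReport(0, 0)
    idx = voxel_indices(cloud.points, params.edge_length)
    _, inverse, counts = np.unique(
        idx, axis=0, return_inverse=True, return_counts=True
    )
    n_vox = len(counts)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, cloud.points)
    centroids = sums / counts[:, None]

    labels_out = None
    if cloud.labels is not None:
        labels_out = np.empty(n_vox, dtype=np.int64)
        order = np.argsort(inverse, kind="stable")
        bounds = np.searchsorted(inverse[order], np.arange(n_vox + 1))
        for v in range(n_vox):
            members = cloud.labels[order[bounds[v] : bounds[v + 1]]]
            vals, cnts = np.unique(members, return_counts=True)
            labels_out[v] = vals[np.argmax(cnts)]  # unique is sorted: ties -> smallest

    out = PointCloud(points=centroids, labels=labels_out)
    return out, FilterReport(n_before=n, n_after=n_vox)


def compression_summary(report: FilterReport) -> float:
    """Percentage of points retained by a filtering stage (100 * after/before)."""
    if report.n_before == 0:
        raise ValueError("empty input cloud: retention undefined")
    return 100.0 * report.n_after / report.n_before
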