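"""Soil-plane fitting (RANSAC), scene leveling and ground removal.

The soil layer dominates a top-view field scan, so a random-sample
consensus plane fit isolates it reliably: triples of points are drawn,
the plane with the largest inlier consensus is kept and refit by total
least squares on its inliers. Leveling rotates the fitted normal onto +Z
and translates the plane to Z = 0; ground removal then drops everything
within a margin of (or below) the plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from canopy_pheno.cloud import PointCloud

DEFAULT_THRESHOLD = 1.0  # cm
DEFAULT_ITERATIONS = 1000
DEFAULT_MARGIN = 1.0  # cm


@dataclass
class PlaneModel:
    """Plane n.p + d = 0 with unit normal (positive Z component)."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray
    inlier_rms: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if not np.isclose(norm, 1.0, atol=1e-9):
            self.normal = self.normal / norm
            self.offset = self.offset / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points).reshape(-1, 3) @ self.normal + self.offset

    def to_dict(self) -> dict:
        return {
            "normal": self.normal.tolist(),
            "offset": float(self.offset),
            "n_inliers": int(len(self.inlier_indices)),
            "inlier_rms": float(self.inlier_rms),
        }


@dataclass
class LevelingTransform:
    """Rigid map p -> R p + t taking the fitted soil plane to Z = 0."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, cloud: PointCloud) -> PointCloud:
        return cloud.transformed(self.rotation, self.translation)


def _fit_plane_tls(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total least squares plane: normal = smallest principal direction."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    return normal, float(-normal @ centroid)


def ransac_plane(
    cloud: PointCloud,
    distance_threshold: float = DEFAULT_THRESHOLD,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> PlaneModel:
    """Best-consensus plane over ``iterations`` random 3-point samples.

    Inliers are points whose absolute signed distance is at most the
    threshold; the winning plane is refit by total least squares on its
    inliers and oriented with a positive Z component.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError(f"plane fit requires at least 3 points, got {n}")
    if distance_threshold <= 0:
        raise ValueError("distance threshold must be positive")
    rng = np.random.default_rng(seed)

    best_count = -1
    best_normal: np.ndarray | None = None
    best_offset = 0.0
    samples = rng.integers(0, n, size=(iterations, 3))
    for tri in samples:
        if len(set(tri.tolist())) < 3:
            continue
        p0, p1, p2 = pts[tri]
        v = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue  # collinear sample
        normal = v / norm
        offset = -normal @ p0
        count = int((np.abs(pts @ normal + offset) <= distance_threshold).sum())
        if count > best_count:
            best_count, best_normal, best_offset = count, normal, offset
    if best_normal is None:
        raise ValueError("all RANSAC samples were degenerate (collinear points)")

    inliers = np.abs(pts @ best_normal + best_offset) <= distance_threshold
    normal, offset = _fit_plane_tls(pts[inliers])
    # refresh the inlier set once with the refit plane
    inliers = np.abs(pts @ normal + offset) <= distance_threshold
    idx = np.flatnonzero(inliers)
    rms = float(np.sqrt(np.mean((pts[idx] @ normal + offset) ** 2))) if len(idx) else 0.0
    return PlaneModel(normal=normal, offset=offset, inlier_indices=idx, inlier_rms=rms)


def leveling_transform(plane: PlaneModel) -> LevelingTransform:
    """Rotation taking the plane normal onto +Z (about their common
    perpendicular) plus the translation putting the plane at Z = 0."""
    n = plane.normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(n @ z)
    if s < 1e-15:
        rotation = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rotation = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    # after rotation the plane is z + d = 0, so shift z up by d
    translation = np.array([0.0, 0.0, plane.offset])
    return LevelingTransform(rotation=rotation, translation=translation)


def level_scene(
    cloud: PointCloud, plane: PlaneModel
) -> tuple[PointCloud, LevelingTransform]:
    """Apply the rigid leveling transform to the whole cloud."""
    transform = leveling_transform(plane)
    return transform.apply(cloud), transform


def remove_ground(
    cloud: PointCloud, plane: PlaneModel, margin: float = DEFAULT_MARGIN
) -> PointCloud:
    """Drop points within ``margin`` of the soil plane or below it.

    Retained points have signed distance > margin; labels are preserved.
    With margin 0 on a noisy scene some ground points survive — expected,
    not an error.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    keep = plane.signed_distance(cloud.points) > margin
    return cloud.select(keep)
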