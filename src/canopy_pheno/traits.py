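"""Per-plant trait extraction: plant height and leaf phenotypes.

Plant height is the vertical extent of the segmented plant (Zmax - Zmin on
a leveled cloud; when the ground reference Z = 0 is supplied, Zmax - 0,
which is the same quantity measured to the soil rather than to the lowest
retained point). Leaves are separated from the stem geometrically, a midrib
polyline is traced along each leaf, and from it come leaf length (midrib
arc length), leaf width (maximum transverse extent), leaf inclination (the
angle theta of the midrib base tangent above the horizontal — the
complement of the stem-leaf angle) and leaf growth height (Z of the
attachment point on the stem).

The stem axis is assumed vertical after leveling (no lodging model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from canopy_pheno.cloud import PointCloud
from canopy_pheno.preprocess import voxel_indices
from canopy_pheno.segmentation import PlantInstance, segment_plants

DEFAULT_STEM_RADIUS = 2.5  # cm: XY distance to the axis counted as stem
DEFAULT_LEAF_CELL = 2.0  # cm: connectivity distance for leaf clustering
DEFAULT_MIN_LEAF_POINTS = 20

VERTICAL = np.array([0.0, 0.0, 1.0])


@dataclass
class LeafSegment:
    """One segmented leaf: member points, ordered midrib, attachment."""

    point_indices: np.ndarray  # indices into the full cloud
    midrib: np.ndarray  # (M, 3) polyline ordered from the stem outward
    attachment: np.ndarray  # (3,) point where the midrib meets the stem axis

    def __post_init__(self) -> None:
        if len(self.midrib) < 2:
            raise ValueError("midrib polyline needs at least 2 vertices")


@dataclass
class LeafTraits:
    leaf_id: int
    length_cm: float
    width_cm: float
    inclination_deg: float
    growth_height_cm: float


@dataclass
class TraitRecord:
    """Extracted phenotypes of one plant."""

    plant_id: int
    height_cm: float
    base_xy: tuple[float, float]
    leaves: list[LeafTraits] = field(default_factory=list)


# ------------------------------------------------------------------ height


def plant_height(
    instance: PlantInstance,
    cloud: PointCloud,
    ground_reference: float | None = None,
) -> float:
    """Plant height in cm: Zmax - Zmin over the instance's points.

    On a leveled cloud whose soil sits at Z = 0, pass
    ``ground_reference=0.0`` to measure Zmax against the soil plane instead
    of the lowest retained point (ground removal strips the stem bottom by
    its margin, so Zmin slightly overestimates the soil there).
    """
    if len(instance.point_indices) == 0:
        raise ValueError("empty plant instance")
    z = cloud.points[instance.point_indices, 2]
    if len(z) == 1:
        warnings.warn("single-point instance: height is 0", stacklevel=2)
    zmin = float(z.min()) if ground_reference is None else float(ground_reference)
    return float(z.max()) - zmin


# ------------------------------------------------------------------ leaves


def estimate_stem_xy(points: np.ndarray, bin_size: float = 2.0) -> np.ndarray:
    """XY of the stem axis: median XY of the densest vertical column.

    The cloud is binned in XY; the bin with the largest vertical extent is
    the stem column (leaves are locally flat, the stem spans the whole
    plant height).
    """
    xy_idx = voxel_indices(points[:, :2], bin_size)
    _, inverse = np.unique(xy_idx, axis=0, return_inverse=True)
    best_bin, best_extent = 0, -1.0
    for b in range(inverse.max() + 1):
        z = points[inverse == b, 2]
        extent = z.max() - z.min()
        if extent > best_extent:
            best_bin, best_extent = b, extent
    seed_xy = np.median(points[inverse == best_bin, :2], axis=0)
    near = np.linalg.norm(points[:, :2] - seed_xy, axis=1) <= 1.5 * bin_size
    return np.median(points[near, :2], axis=0)


def _cluster_points(points: np.ndarray, cell: float, min_pts: int) -> list[np.ndarray]:
    """Connectivity clustering helper returning index arrays (local)."""
    cloud = PointCloud(points=points)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        instances = segment_plants(cloud, cell_size=cell, min_points=min_pts)
    return [inst.point_indices for inst in instances]


def _midrib_from_points(
    pts: np.ndarray, stem_xy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered midrib polyline and attachment point for one leaf cluster.

    Points are ordered along the first principal direction and averaged in
    transverse slices (one per cm or 20 slices, whichever is finer); the
    attachment is the base of the midrib extrapolated onto the vertical
    stem axis.
    """
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    axis = vt[0]
    t = (pts - centroid) @ axis
    # orient the axis away from the stem
    far_xy = pts[np.argmax(t), :2]
    near_xy = pts[np.argmin(t), :2]
    if np.linalg.norm(far_xy - stem_xy) < np.linalg.norm(near_xy - stem_xy):
        axis, t = -axis, -t
    length_est = t.max() - t.min()
    n_slices = max(20, int(math.ceil(length_est)))
    edges = np.linspace(t.min(), t.max(), n_slices + 1)
    which = np.clip(np.digitize(t, edges) - 1, 0, n_slices - 1)
    verts = []
    for s in range(n_slices):
        members = pts[which == s]
        if len(members):
            verts.append(members.mean(axis=0))
    midrib = np.asarray(verts)

    # extrapolate the midrib back to the stem axis (XY distance 0): fit
    # height against radial distance over the basal vertices (quadratic for
    # an arched midrib) and take the intercept as the attachment height
    h = np.linalg.norm(midrib[:, :2] - stem_xy, axis=1)
    basal = h <= max(0.4 * h.max(), np.sort(h)[min(3, len(h) - 1)])
    attach = np.array([stem_xy[0], stem_xy[1], midrib[0, 2]])
    if basal.sum() >= 4:
        attach[2] = float(np.polyfit(h[basal], midrib[basal, 2], 2)[2])
    elif basal.sum() >= 2:
        attach[2] = float(np.polyfit(h[basal], midrib[basal, 2], 1)[1])
    return midrib, attach


def extract_leaves(
    instance: PlantInstance,
    cloud: PointCloud,
    stem_radius: float = DEFAULT_STEM_RADIUS,
    cell_size: float = DEFAULT_LEAF_CELL,
    min_leaf_points: int = DEFAULT_MIN_LEAF_POINTS,
) -> list[LeafSegment]:
    """Split a segmented plant into stem and leaves and trace each midrib.

    Points within ``stem_radius`` (XY) of the estimated stem axis are stem;
    the rest are clustered by connectivity at ``cell_size`` into leaves
    (opposite leaves at the same height separate azimuthally). Returns an
    empty list for a leafless stem.
    """
    pts = cloud.points[instance.point_indices]
    if len(pts) < 4:
        return []
    stem_xy = estimate_stem_xy(pts)
    off_stem = np.linalg.norm(pts[:, :2] - stem_xy, axis=1) > stem_radius
    if not off_stem.any():
        return []
    off_idx = np.flatnonzero(off_stem)
    leaves = []
    for local in _cluster_points(pts[off_idx], cell_size, min_leaf_points):
        leaf_pts = pts[off_idx[local]]
        midrib, attach = _midrib_from_points(leaf_pts, stem_xy)
        if len(midrib) < 2:
            continue
        leaves.append(
            LeafSegment(
                point_indices=instance.point_indices[off_idx[local]],
                midrib=np.vstack([attach, midrib]),
                attachment=attach,
            )
        )
    leaves.sort(key=lambda s: s.attachment[2])
    return leaves


def leaf_length(leaf: LeafSegment) -> float:
    """Midrib arc length from attachment to tip, in cm."""
    seg = np.diff(leaf.midrib, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def leaf_width(leaf: LeafSegment, cloud: PointCloud) -> float:
    """Maximum transverse extent over midrib slices, in cm."""
    pts = cloud.points[leaf.point_indices]
    if len(pts) < 3:
        raise ValueError("leaf width needs at least 3 points")
    mid = leaf.midrib
    tangents = np.gradient(mid, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    # assign each point to its nearest midrib vertex
    d2 = ((pts[:, None, :] - mid[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    width = 0.0
    for v in range(len(mid)):
        members = pts[nearest == v]
        if len(members) < 2:
            continue
        r = members - mid[v]
        r_perp = r - np.outer(r @ tangents[v], tangents[v])
        # extent along the principal transverse direction
        _, _, vt = np.linalg.svd(r_perp - r_perp.mean(axis=0), full_matrices=False)
        proj = r_perp @ vt[0]
        width = max(width, float(proj.max() - proj.min()))
    if width == 0.0:
        raise ValueError("degenerate leaf: no transverse extent")
    return width


def leaf_inclination(leaf: LeafSegment, stem_axis: np.ndarray = VERTICAL) -> float:
    """Leaf inclination theta in degrees: 90 minus the stem-leaf angle.

    The stem-leaf angle is measured between the stem axis and the midrib
    tangent at the attachment; theta is its complement, clamped to
    [0, 90] — equivalently the angle of the leaf base above the horizontal
    plane. Because maize midribs droop smoothly, the base tangent is
    estimated by fitting a quadratic to height vs. radial distance over the
    basal part of the midrib and differentiating at the stem, which is
    unbiased for an arched midrib (a secant through basal vertices would
    systematically underestimate erect leaves).
    """
    mid = leaf.midrib
    radial = mid[:, :2] - leaf.attachment[None, :2]
    h = np.linalg.norm(radial, axis=1)
    if h.max() < 1e-12:
        raise ValueError("zero-length midrib base tangent")
    basal = (h > 1e-9) & (
        h <= max(0.4 * h.max(), np.sort(h)[min(4, len(h) - 1)])
    )
    if basal.sum() < 2:
        basal = h > 1e-9
    hs, zs = h[basal], mid[basal, 2]
    if basal.sum() >= 4:
        slope = float(np.polyfit(hs, zs, 2)[1])
    else:
        slope = float(np.polyfit(hs, zs, 1)[0])
    u = radial[np.argmax(h)] / h.max()  # outward horizontal direction
    tangent = np.array([u[0], u[1], slope])
    tangent = tangent / np.linalg.norm(tangent)
    axis = np.asarray(stem_axis, float)
    axis = axis / np.linalg.norm(axis)
    stem_leaf = math.degrees(math.acos(min(1.0, abs(float(tangent @ axis)))))
    return float(np.clip(90.0 - stem_leaf, 0.0, 90.0))


def leaf_growth_height(leaf: LeafSegment) -> float:
    """Height of the attachment point above the (leveled) ground, in cm."""
    z = float(leaf.attachment[2])
    if z < 0:
        warnings.warn(
            f"leaf attachment below ground (Z={z:.2f} cm): check leveling",
            stacklevel=2,
        )
    return z


# ------------------------------------------------------------------ tables


def extract_traits(
    instance: PlantInstance,
    cloud: PointCloud,
    ground_reference: float | None = None,
    **leaf_kwargs,
) -> TraitRecord:
    """All phenotypes of one plant; leaf failures degrade to fewer leaves."""
    record = TraitRecord(
        plant_id=instance.instance_id,
        height_cm=plant_height(instance, cloud, ground_reference=ground_reference),
        base_xy=instance.base_xy,
    )
    for lid, leaf in enumerate(extract_leaves(instance, cloud, **leaf_kwargs), start=1):
        try:
            record.leaves.append(
                LeafTraits(
                    leaf_id=lid,
                    length_cm=leaf_length(leaf),
                    width_cm=leaf_width(leaf, cloud),
                    inclination_deg=leaf_inclination(leaf),
                    growth_height_cm=leaf_growth_height(leaf),
                )
            )
        except ValueError:
            continue
    return record


def traits_frame(records: list[TraitRecord]) -> pd.DataFrame:
    """Long-format trait table, one row per leaf (plants without extracted
    leaves contribute a single row with leaf columns empty)."""
    rows = []
    for rec in records:
        if not rec.leaves:
            rows.append(
                dict(plant_id=rec.plant_id, height_cm=rec.height_cm, leaf_id=0,
                     length_cm=np.nan, width_cm=np.nan, inclination_deg=np.nan,
                     growth_height_cm=np.nan)
            )
        for lt in rec.leaves:
            rows.append(
                dict(plant_id=rec.plant_id, height_cm=rec.height_cm,
                     leaf_id=lt.leaf_id, length_cm=lt.length_cm,
                     width_cm=lt.width_cm, inclination_deg=lt.inclination_deg,
                     growth_height_cm=lt.growth_height_cm)
            )
    return pd.DataFrame(rows)
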