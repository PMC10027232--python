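"""Sphere-target scale calibration and DLT image/cloud registration.

Two spheres of known diameter (250 mm and 200 mm targets, i.e. 25 and 20 cm)
placed in the scanned scene give a fixed-scale reference: fitting each
sphere and comparing fitted to known diameters yields a global scale
correction. Registration between 2D image coordinates and 3D cloud
coordinates uses the 11-parameter direct linear transformation

    x = -(l1 X + l2 Y + l3 Z + l4) / (l9 X + l10 Y + l11 Z + 1)
    y = -(l5 X + l6 Y + l7 Z + l8) / (l9 X + l10 Y + l11 Z + 1)

solved by linear least squares from >= 6 non-coplanar point
correspondences, with no initial values required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from canopy_pheno.cloud import PointCloud


@dataclass
class SphereFit:
    """Least-squares sphere: center, radius, RMS residual (all cm)."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class ScaleCalibration:
    """Global scale correction derived from calibration-sphere fits."""

    scale: float
    pairs: list[tuple[float, float]]  # (known diameter, fitted diameter) cm

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class Correspondence:
    """One 2D (pixels) to 3D (cm) feature-point correspondence."""

    image_xy: tuple[float, float]
    object_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = (*self.image_xy, *self.object_xyz)
        if not np.all(np.isfinite(vals)):
            raise ValueError("correspondence contains non-finite values")


@dataclass
class DLTModel:
    """The 11 DLT parameters l1..l11 and the reprojection RMS in pixels."""

    params: np.ndarray  # shape (11,)
    reprojection_rms: float

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64).reshape(11)

    def to_json(self) -> str:
        return json.dumps(
            {
                **{f"l{i + 1}": float(v) for i, v in enumerate(self.params)},
                "reprojection_rms": self.reprojection_rms,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DLTModel":
        d = json.loads(text)
        return cls(
            params=np.array([d[f"l{i + 1}"] for i in range(11)]),
            reprojection_rms=float(d.get("reprojection_rms", float("nan"))),
        )


# ------------------------------------------------------------------ spheres


def fit_sphere(points: np.ndarray | PointCloud, refine: bool = True) -> SphereFit:
    """Fit a sphere to >= 4 non-coplanar points by least squares.

    An algebraic linear solve (|p|^2 = 2 c.p + r^2 - |c|^2) provides the
    starting values; a Gauss-Newton refinement of the geometric distance
    (at most 50 iterations, tolerance 1e-10) polishes them.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    pts = pts.reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError(f"insufficient points for sphere fit: {len(pts)} < 4")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) point configuration for sphere fit")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))

    if refine:
        for _ in range(50):
            diff = pts - center
            dist = np.linalg.norm(diff, axis=1)
            if np.any(dist == 0):
                break
            res = dist - radius
            # Jacobian of residuals wrt (cx, cy, cz, r)
            J = np.column_stack([-diff / dist[:, None], -np.ones(len(pts))])
            try:
                delta = np.linalg.lstsq(J, -res, rcond=None)[0]
            except np.linalg.LinAlgError:
                break
            center = center + delta[:3]
            radius = float(radius + delta[3])
            if np.linalg.norm(delta) < 1e-10:
                break

    dist = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms, n_points=len(pts))


def calibrate_scale(
    fits: list[SphereFit] | list[float], known_diameters: list[float]
) -> ScaleCalibration:
    """Mean-of-ratios global scale from (fitted, known) diameter pairs."""
    fitted = [f.diameter if isinstance(f, SphereFit) else float(f) for f in fits]
    if len(fitted) != len(known_diameters):
        raise ValueError("fitted and known diameter lists differ in length")
    if not fitted:
        raise ValueError("at least one sphere is required for scale calibration")
    if any(d <= 0 for d in fitted):
        raise ValueError("non-positive fitted diameter")
    ratios = [k / f for k, f in zip(known_diameters, fitted)]
    return ScaleCalibration(
        scale=float(np.mean(ratios)), pairs=list(zip(known_diameters, fitted))
    )


def apply_scale(cloud: PointCloud, calibration: ScaleCalibration) -> PointCloud:
    """Scale all coordinates about the cloud centroid (diameter-only targets
    cannot fix a datum, so the centroid is kept in place)."""
    centroid = cloud.points.mean(axis=0) if len(cloud) else np.zeros(3)
    pts = centroid + calibration.scale * (cloud.points - centroid)
    return PointCloud(points=pts, intensity=cloud.intensity, labels=cloud.labels)


# ------------------------------------------------------------------ DLT

_MIN_CORRESPONDENCES = 6


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform (homogeneous) centering points at the origin with
    RMS distance sqrt(dim); standard conditioning for the linear DLT solve."""
    pts = np.asarray(pts, float)
    dim = pts.shape[1]
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    s = np.sqrt(dim) / rms if rms > 0 else 1.0
    T = np.eye(dim + 1)
    T[:dim, :dim] *= s
    T[:dim, dim] = -s * centroid
    return T


def solve_dlt(correspondences: list[Correspondence]) -> DLTModel:
    """Solve the 11 DLT parameters from >= 6 correspondences.

    Clearing denominators gives two linear equations per correspondence in
    l1..l11; the system is solved by least squares on normalized
    coordinates and the similarity transforms are undone afterwards.
    Coplanar object points make the model unobservable and are rejected.
    """
    if len(correspondences) < _MIN_CORRESPONDENCES:
        raise ValueError(
            f"at least {_MIN_CORRESPONDENCES} correspondences required, "
            f"got {len(correspondences)}"
        )
    obj = np.array([c.object_xyz for c in correspondences], dtype=float)
    img = np.array([c.image_xy for c in correspondences], dtype=float)

    # coplanarity check on the object points
    centered = obj - obj.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[2] < 1e-8 * max(svals[0], 1.0):
        raise ValueError("degenerate configuration: object points are coplanar")

    Tobj = _normalization(obj)
    Timg = _normalization(img)
    objn = (np.column_stack([obj, np.ones(len(obj))]) @ Tobj.T)[:, :3]
    imgn = (np.column_stack([img, np.ones(len(img))]) @ Timg.T)[:, :2]

    # x + (l1 X + l2 Y + l3 Z + l4)/(l9 X + l10 Y + l11 Z + 1) = 0
    # => l1 X + l2 Y + l3 Z + l4 + x (l9 X + l10 Y + l11 Z) = -x
    n = len(objn)
    A = np.zeros((2 * n, 11))
    b = np.zeros(2 * n)
    X, Y, Z = objn[:, 0], objn[:, 1], objn[:, 2]
    x, y = imgn[:, 0], imgn[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2], A[0::2, 3] = X, Y, Z, 1.0
    A[0::2, 8], A[0::2, 9], A[0::2, 10] = x * X, x * Y, x * Z
    b[0::2] = -x
    A[1::2, 4], A[1::2, 5], A[1::2, 6], A[1::2, 7] = X, Y, Z, 1.0
    A[1::2, 8], A[1::2, 9], A[1::2, 10] = y * X, y * Y, y * Z
    b[1::2] = -y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 11:
        raise ValueError("degenerate configuration: DLT design matrix rank-deficient")

    # undo normalization: homogeneously (x, y, 1) ~ M q with
    # M = [-l1..-l4; -l5..-l8; l9 l10 l11 1], so M = Timg^-1 Mn Tobj,
    # rescaled to keep M[2,3] = 1, then the signs are peeled back off.
    Mn = np.vstack(
        [
            [-sol[0], -sol[1], -sol[2], -sol[3]],
            [-sol[4], -sol[5], -sol[6], -sol[7]],
            [sol[8], sol[9], sol[10], 1.0],
        ]
    )
    M = np.linalg.inv(Timg) @ Mn @ Tobj
    if abs(M[2, 3]) < 1e-14:
        raise ValueError("degenerate DLT solution (vanishing normalizer)")
    M = M / M[2, 3]
    params = np.concatenate([-M[0], -M[1], M[2, :3]])

    model = DLTModel(params=params, reprojection_rms=0.0)
    proj = project_dlt(model, obj)
    model.reprojection_rms = float(np.sqrt(np.mean(np.sum((proj - img) ** 2, axis=1))))
    return model


def project_dlt(model: DLTModel, object_point: np.ndarray) -> np.ndarray:
    """Forward DLT projection of one point (3,) or many (N, 3) to pixels."""
    p = np.asarray(object_point, dtype=float)
    single = p.ndim == 1
    p = p.reshape(-1, 3)
    l = model.params
    den = p @ l[8:11] + 1.0
    if np.any(np.abs(den) < 1e-12):
        raise ValueError("vanishing DLT denominator at the requested point")
    x = -(p @ l[0:3] + l[3]) / den
    y = -(p @ l[4:7] + l[7]) / den
    out = np.column_stack([x, y])
    return out[0] if single else out
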