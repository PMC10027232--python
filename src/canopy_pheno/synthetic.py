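"""Ground-truthed synthetic maize canopy scenes.

Every downstream stage of the pipeline is validated against scenes produced
here, because no public scan of the original field exists. A scene consists
of a gently sloped, rough soil plane, maize plants with fully known geometry
(stem height, per-leaf length / width / inclination / growth height), two
calibration spheres resting on the soil, isotropic Gaussian sensor noise and
uniform box outliers.

Plant model
-----------
The stem is a vertical cylinder. Each leaf is a ruled strip around an arched
midrib: the midrib leaves the stem at the leaf's growth height, pointing
along the azimuth at the stated inclination above the horizontal, and droops
quadratically (the ``arch`` coefficient is the tip droop as a fraction of
the leaf length). Width tapers linearly from the base to a maximum at one
third of the length and then to a sharp tip, a common maize idealization.
This makes every reported trait analytically known: leaf length is the
midrib arc length (enforced exactly when the midrib is built), width is the
maximum transverse extent, inclination is the angle of the midrib's base
tangent above the horizontal.

Plants are grown along the local soil normal, so leveling the scene restores
the canonical upright geometry exactly; at the few-degree slopes emulated
here the difference from gravity-vertical growth is negligible.

Sampling is a deterministic surface grid at ``density`` points/cm^2
(default 4, LiDAR-like); the random seed drives noise, outliers and the
randomized plant specs only, so a seeded scene regenerates identically.

Point labels: 0 = ground, 1..P = plant instance, 1000+k = calibration
sphere k (1-based), -1 = outlier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from canopy_pheno.cloud import PointCloud

SPHERE_LABEL_BASE = 1000
OUTLIER_LABEL = -1

#: default calibration-sphere diameters in cm (250 mm and 200 mm targets)
DEFAULT_SPHERE_DIAMETERS = (25.0, 20.0)


@dataclass
class LeafSpec:
    """Geometry of one leaf, all lengths in cm, angles in degrees."""

    growth_height: float  # attachment height on the stem
    azimuth: float  # direction the leaf points, degrees from +X
    length: float  # midrib arc length
    width: float  # maximum blade width
    inclination: float  # base-tangent angle above horizontal, in [0, 90]
    arch: float = 0.15  # tip droop as a fraction of length (>= 0)

    def __post_init__(self) -> None:
        if not (self.length > self.width > 0):
            raise ValueError("leaf requires length > width > 0")
        if not (0.0 <= self.inclination <= 90.0):
            raise ValueError("inclination must be in [0, 90] degrees")
        if self.arch < 0:
            raise ValueError("arch must be non-negative")


@dataclass
class PlantSpec:
    """One maize plant: stem base, height, radius and its leaves."""

    base_xy: tuple[float, float]
    height: float
    stem_radius: float = 1.2
    leaves: list[LeafSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("plant height must be positive")
        for leaf in self.leaves:
            if leaf.growth_height >= self.height:
                raise ValueError("leaf growth height must be below plant height")


@dataclass
class SceneSpec:
    """Layout and nuisance parameters of a synthetic canopy scene.

    Defaults emulate a jointing-stage breeding plot scanned from above:
    ~80 cm plants on a 60 cm grid (well separated, as in sparse-density
    plots), a soil plane with a 2 degree slope and 0.2 cm roughness, the
    two 25 / 20 cm calibration spheres, 0.1 cm sensor noise and a handful
    of stray outlier returns.
    """

    rows: int = 2
    plants_per_row: int = 3
    plant_spacing: float = 60.0  # cm along a row
    row_spacing: float = 60.0  # cm between rows
    ground_slope: float = 2.0  # degrees, about the Y axis
    ground_roughness: float = 0.2  # cm, sigma of soil micro-relief
    sphere_diameters: tuple[float, ...] = DEFAULT_SPHERE_DIAMETERS  # cm
    noise_sigma: float = 0.1  # cm, isotropic sensor noise
    n_outliers: int = 30
    mean_height: float = 80.0  # cm, mean plant height
    height_sd: float = 4.0
    leaves_per_plant: int = 4
    density: float = 4.0  # points/cm^2 on plant surfaces
    ground_density: float = 1.0  # points/cm^2 on the soil
    margin: float = 40.0  # cm of bare soil around the planted grid
    seed: int = 0
    plants: list[PlantSpec] | None = None  # explicit plants override layout

    def __post_init__(self) -> None:
        if self.plant_spacing <= 0 or self.row_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.noise_sigma < 0 or self.ground_roughness < 0:
            raise ValueError("noise levels must be non-negative")
        if self.density <= 0 or self.ground_density <= 0:
            raise ValueError("densities must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SceneSpec":
        data = dict(data)
        if data.get("plants"):
            data["plants"] = [
                PlantSpec(
                    base_xy=tuple(p["base_xy"]),
                    height=p["height"],
                    stem_radius=p.get("stem_radius", 1.2),
                    leaves=[LeafSpec(**l) for l in p.get("leaves", [])],
                )
                for p in data["plants"]
            ]
        if "sphere_diameters" in data:
            data["sphere_diameters"] = tuple(data["sphere_diameters"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-point and per-plant truth for a generated scene."""

    plants: list[PlantSpec]
    labels: np.ndarray  # instance labels, one per point (encoding above)
    leaf_labels: np.ndarray  # within-plant part id: 0 stem, 1.. leaf index
    plane_normal: np.ndarray  # unit normal of the true soil plane
    plane_offset: float  # d with n.p + d = 0 on the plane
    sphere_centers: np.ndarray  # (S, 3)
    sphere_diameters: np.ndarray  # (S,)

    def trait_frame(self) -> pd.DataFrame:
        """True trait table: one row per leaf plus a leafless height row."""
        rows = []
        for pid, plant in enumerate(self.plants, start=1):
            if not plant.leaves:
                rows.append(
                    dict(plant_id=pid, height_cm=plant.height, leaf_id=0,
                         length_cm=np.nan, width_cm=np.nan,
                         inclination_deg=np.nan, growth_height_cm=np.nan)
                )
            for lid, leaf in enumerate(plant.leaves, start=1):
                rows.append(
                    dict(plant_id=pid, height_cm=plant.height, leaf_id=lid,
                         length_cm=leaf.length, width_cm=leaf.width,
                         inclination_deg=leaf.inclination,
                         growth_height_cm=leaf.growth_height)
                )
        return pd.DataFrame(rows)

    def label_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"point_id": np.arange(len(self.labels)), "label": self.labels}
        )


# ------------------------------------------------------------------ midrib


def _midrib_extent(length: float, incl_rad: float, arch: float) -> float:
    """Solve for the parameter range q_max giving midrib arc length ``length``.

    The midrib is c(q) = q*(cos i, 0, sin i) - arch*length*(q/q_max)^2 * e_z
    in its own vertical plane; arc length grows monotonically with q_max.
    """
    droop = arch * length  # total tip droop, cm

    def arc(qm: float) -> float:
        def speed(q: float) -> float:
            dz = math.sin(incl_rad) - 2.0 * droop * q / qm**2
            return math.hypot(math.cos(incl_rad), dz)

        return quad(speed, 0.0, qm, limit=200)[0]

    lo = length * 0.05
    hi = length * 1.5
    while arc(hi) < length:
        hi *= 2.0
    while arc(lo) > length:
        lo *= 0.5
    return brentq(lambda qm: arc(qm) - length, lo, hi, xtol=1e-10)


def midrib_polyline(
    leaf: LeafSpec, attach: np.ndarray, n: int = 200
) -> np.ndarray:
    """Analytic midrib of a leaf, ordered from the attachment outward."""
    incl = math.radians(leaf.inclination)
    az = math.radians(leaf.azimuth)
    u = np.array([math.cos(az), math.sin(az), 0.0])
    qm = _midrib_extent(leaf.length, incl, leaf.arch)
    droop = leaf.arch * leaf.length
    q = np.linspace(0.0, qm, n)
    pts = (
        attach[None, :]
        + q[:, None] * (math.cos(incl) * u + math.sin(incl) * np.array([0, 0, 1.0]))[None, :]
        - (droop * (q / qm) ** 2)[:, None] * np.array([0, 0, 1.0])[None, :]
    )
    return pts


def leaf_apex_height(leaf: LeafSpec) -> float:
    """Highest point of the midrib above the attachment, in cm."""
    pts = midrib_polyline(leaf, np.zeros(3), n=400)
    return float(pts[:, 2].max())


def _width_profile(s_frac: np.ndarray, width: float) -> np.ndarray:
    """Blade width at fractional arc position: base 0.4W, peak W at 1/3, sharp tip."""
    w = np.where(
        s_frac <= 1.0 / 3.0,
        0.4 + 0.6 * (s_frac * 3.0),
        1.0 - 0.98 * (s_frac - 1.0 / 3.0) * 1.5,
    )
    return width * np.clip(w, 0.02, 1.0)


# ------------------------------------------------------------------ plants


def generate_plant(
    spec: PlantSpec, density: float = 4.0, seed: int | None = None
) -> PointCloud:
    """Sample a single plant as a surface point cloud at ``density`` pts/cm^2.

    The cloud is a deterministic grid sample of the stem cylinder and leaf
    strips (the same spec always yields the same cloud); ``seed`` is kept in
    the signature for forward compatibility with jittered sampling and is
    unused by the grid sampler. Point labels give the part: 0 for stem,
    k for the k-th leaf (1-based).

    The highest noiseless point equals the stem top (base Z + height)
    exactly, because the top stem ring is always sampled.
    """
    if density <= 0:
        raise ValueError("point density must be positive")
    step = 1.0 / math.sqrt(density)
    bx, by = spec.base_xy
    parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    # stem: lateral surface of a vertical cylinder, top ring included
    n_h = max(2, int(round(spec.height / step)) + 1)
    n_ang = max(4, int(round(2.0 * math.pi * spec.stem_radius / step)))
    heights = np.linspace(0.0, spec.height, n_h)
    angles = np.linspace(0.0, 2.0 * math.pi, n_ang, endpoint=False)
    hh, aa = np.meshgrid(heights, angles, indexing="ij")
    stem = np.column_stack(
        [
            bx + spec.stem_radius * np.cos(aa).ravel(),
            by + spec.stem_radius * np.sin(aa).ravel(),
            hh.ravel(),
        ]
    )
    parts.append(stem)
    labels.append(np.zeros(len(stem), dtype=np.int64))

    for k, leaf in enumerate(spec.leaves, start=1):
        if leaf.growth_height + leaf_apex_height(leaf) > spec.height + 1e-9:
            warnings.warn(
                f"leaf {k} apex exceeds plant height; cloud max Z will be the leaf",
                stacklevel=2,
            )
        attach = np.array([bx, by, leaf.growth_height])
        n_s = max(2, int(round(leaf.length / step)) + 1)
        mid = midrib_polyline(leaf, attach, n=n_s)
        s_frac = np.linspace(0.0, 1.0, n_s)
        w = _width_profile(s_frac, leaf.width)
        az = math.radians(leaf.azimuth)
        v = np.array([-math.sin(az), math.cos(az), 0.0])  # transverse, horizontal
        pts = []
        for c, wi in zip(mid, w):
            n_t = max(2, int(round(wi / step)) + 1)
            t = np.linspace(-wi / 2.0, wi / 2.0, n_t)
            pts.append(c[None, :] + t[:, None] * v[None, :])
        leaf_pts = np.vstack(pts)
        parts.append(leaf_pts)
        labels.append(np.full(len(leaf_pts), k, dtype=np.int64))

    return PointCloud(points=np.vstack(parts), labels=np.concatenate(labels))


def random_plant_spec(
    base_xy: tuple[float, float],
    rng: np.random.Generator,
    mean_height: float = 80.0,
    height_sd: float = 4.0,
    n_leaves: int = 4,
) -> PlantSpec:
    """Draw a realistic jointing-stage plant with leaves kept below the stem top.

    Maize phyllotaxy is distichous: successive leaves alternate sides with a
    small azimuthal jitter. Leaf size scales with the plant.
    """
    height = float(np.clip(rng.normal(mean_height, height_sd), 40.0, None))
    base_az = rng.uniform(0.0, 360.0)
    leaves = []
    for k in range(n_leaves):
        frac = 0.25 + 0.5 * (k + rng.uniform(-0.2, 0.2)) / max(n_leaves - 1, 1)
        growth = float(np.clip(frac, 0.15, 0.85)) * height
        azimuth = (base_az + 180.0 * k + rng.uniform(-25.0, 25.0)) % 360.0
        length = float(rng.uniform(0.25, 0.34)) * height * 0.85
        width = float(rng.uniform(0.14, 0.20)) * length
        inclination = float(rng.uniform(20.0, 45.0))
        arch = float(rng.uniform(0.10, 0.25))
        leaf = LeafSpec(
            growth_height=growth,
            azimuth=azimuth,
            length=length,
            width=width,
            inclination=inclination,
            arch=arch,
        )
        # keep the stem top the highest point of the plant
        while growth + leaf_apex_height(leaf) > 0.97 * height and leaf.inclination > 5.0:
            leaf.inclination = max(5.0, leaf.inclination - 5.0)
        if growth + leaf_apex_height(leaf) > 0.97 * height:
            leaf.length = 0.97 * leaf.length
        leaves.append(leaf)
    return PlantSpec(base_xy=base_xy, height=height, leaves=leaves)


# ------------------------------------------------------------------ scenes


def _slope_rotation(slope_deg: float) -> np.ndarray:
    """Rotation about the Y axis tilting +Z into the soil normal."""
    a = math.radians(slope_deg)
    return np.array(
        [
            [math.cos(a), 0.0, math.sin(a)],
            [0.0, 1.0, 0.0],
            [-math.sin(a), 0.0, math.cos(a)],
        ]
    )


def _sample_sphere(
    center: np.ndarray, radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return center[None, :] + radius * d


def generate_scene(spec: SceneSpec) -> tuple[PointCloud, GroundTruth]:
    """Build a full canopy scene and its ground truth.

    The soil is the plane through the origin whose normal is +Z tilted by
    ``ground_slope`` about the Y axis; plants and spheres sit on it (plants
    grown along the normal, spheres tangent). Gaussian sensor noise of
    ``noise_sigma`` is added to every surface point; outliers are appended
    uniformly inside the scene bounding box. The returned cloud carries the
    instance labels (also available in the ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    rot = _slope_rotation(spec.ground_slope)
    normal = rot @ np.array([0.0, 0.0, 1.0])

    if spec.plants is not None:
        plants = spec.plants
        xs = [p.base_xy[0] for p in plants]
        ys = [p.base_xy[1] for p in plants]
        xmin, xmax = min(xs) - spec.margin, max(xs) + spec.margin
        ymin, ymax = min(ys) - spec.margin, max(ys) + spec.margin
    else:
        plants = []
        for r in range(spec.rows):
            for c in range(spec.plants_per_row):
                base = (
                    c * spec.plant_spacing + rng.uniform(-2.0, 2.0),
                    r * spec.row_spacing + rng.uniform(-2.0, 2.0),
                )
                plants.append(
                    random_plant_spec(
                        base,
                        rng,
                        mean_height=spec.mean_height,
                        height_sd=spec.height_sd,
                        n_leaves=spec.leaves_per_plant,
                    )
                )
        xmin = -spec.margin
        xmax = (spec.plants_per_row - 1) * spec.plant_spacing + spec.margin
        ymin = -spec.margin
        ymax = (spec.rows - 1) * spec.row_spacing + spec.margin

    parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    leaf_labels: list[np.ndarray] = []

    # soil: grid in plane coordinates, displaced along the normal by roughness
    step = 1.0 / math.sqrt(spec.ground_density)
    gx = np.arange(xmin, xmax + step, step)
    gy = np.arange(ymin, ymax + step, step)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    plane_pts = np.column_stack(
        [gxx.ravel(), gyy.ravel(), np.zeros(gxx.size)]
    ) @ rot.T
    if spec.ground_roughness > 0:
        plane_pts += (
            rng.normal(0.0, spec.ground_roughness, size=(len(plane_pts), 1))
            * normal[None, :]
        )
    parts.append(plane_pts)
    labels.append(np.zeros(len(plane_pts), dtype=np.int64))
    leaf_labels.append(np.zeros(len(plane_pts), dtype=np.int64))

    # plants: canonical upright sample, then rotated onto the sloped soil
    for pid, plant in enumerate(plants, start=1):
        canonical = PlantSpec(
            base_xy=(0.0, 0.0),
            height=plant.height,
            stem_radius=plant.stem_radius,
            leaves=plant.leaves,
        )
        cloud = generate_plant(canonical, density=spec.density)
        base = rot @ np.array([plant.base_xy[0], plant.base_xy[1], 0.0])
        pts = cloud.points @ rot.T + base[None, :]
        parts.append(pts)
        labels.append(np.full(len(pts), pid, dtype=np.int64))
        leaf_labels.append(cloud.labels)

    # calibration spheres in bare corners, tangent to the soil plane
    sphere_centers = []
    corner_xy = [
        (xmin + spec.margin * 0.4, ymin + spec.margin * 0.4),
        (xmax - spec.margin * 0.4, ymin + spec.margin * 0.4),
        (xmin + spec.margin * 0.4, ymax - spec.margin * 0.4),
        (xmax - spec.margin * 0.4, ymax - spec.margin * 0.4),
    ]
    for k, dia in enumerate(spec.sphere_diameters, start=1):
        radius = dia / 2.0
        cx, cy = corner_xy[(k - 1) % len(corner_xy)]
        center = rot @ np.array([cx, cy, 0.0]) + radius * normal
        n_pts = max(50, int(round(spec.density * 4.0 * math.pi * radius**2)))
        pts = _sample_sphere(center, radius, n_pts, rng)
        parts.append(pts)
        labels.append(np.full(len(pts), SPHERE_LABEL_BASE + k, dtype=np.int64))
        leaf_labels.append(np.zeros(len(pts), dtype=np.int64))
        sphere_centers.append(center)

    points = np.vstack(parts)
    if spec.noise_sigma > 0:
        points = points + rng.normal(0.0, spec.noise_sigma, size=points.shape)

    if spec.n_outliers > 0:
        zmax = max(p.height for p in plants) * 1.5 if plants else 100.0
        out = np.column_stack(
            [
                rng.uniform(xmin, xmax, spec.n_outliers),
                rng.uniform(ymin, ymax, spec.n_outliers),
                rng.uniform(5.0, zmax, spec.n_outliers),
            ]
        )
        points = np.vstack([points, out])
        labels.append(np.full(spec.n_outliers, OUTLIER_LABEL, dtype=np.int64))
        leaf_labels.append(np.zeros(spec.n_outliers, dtype=np.int64))

    all_labels = np.concatenate(labels)
    truth = GroundTruth(
        plants=list(plants),
        labels=all_labels,
        leaf_labels=np.concatenate(leaf_labels),
        plane_normal=normal,
        plane_offset=0.0,
        sphere_centers=np.array(sphere_centers).reshape(-1, 3),
        sphere_diameters=np.asarray(spec.sphere_diameters, dtype=float),
    )
    return PointCloud(points=points, labels=all_labels.copy()), truth
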