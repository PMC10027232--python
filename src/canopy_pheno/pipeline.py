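"""End-to-end orchestration: scene in, trait table and reports out.

The pipeline chains the stages in the order the platform processes a scan:
statistical outlier filtering, voxel down-sampling, RANSAC soil-plane fit,
leveling, ground removal, plant instance segmentation and trait extraction,
optionally followed by validation against a synthetic scene's ground truth.
Every stage logs its point counts; a manifest records parameters and the
seed so a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from canopy_pheno import io
from canopy_pheno.cloud import PointCloud
from canopy_pheno.evaluation import EvalReport, PairedMeasurements, evaluate_pairs
from canopy_pheno.ground import level_scene, ransac_plane, remove_ground
from canopy_pheno.preprocess import (
    VoxelParams,
    statistical_outlier_removal,
    voxel_downsample,
)
from canopy_pheno.segmentation import assign_plots, instances_frame, segment_plants
from canopy_pheno.synthetic import GroundTruth, SceneSpec, generate_scene
from canopy_pheno.traits import TraitRecord, extract_traits, traits_frame

logger = logging.getLogger("canopy_pheno.pipeline")

_TRAIT_COLUMNS = [
    "length_cm",
    "width_cm",
    "inclination_deg",
    "growth_height_cm",
]


@dataclass
class PipelineConfig:
    """All stage parameters plus the input specification.

    Exactly one of ``scene`` (synthetic scene spec) or ``input_cloud``
    (path to an xyz/ply/pcd file) must be provided. Unknown keys in a
    config file are rejected.
    """

    scene: dict | None = None
    input_cloud: str | None = None
    plot_map: str | None = None
    sor_k: int = 20
    sor_std: float = 2.0
    voxel_edge: float = 0.5
    ransac_threshold: float = 1.0
    ransac_iterations: int = 1000
    ground_margin: float = 1.0
    cell_size: float = 5.0
    min_points: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scene is None) == (self.input_cloud is None):
            raise ValueError("provide exactly one of 'scene' or 'input_cloud'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def _is_calibration_sphere(cloud: PointCloud, instance) -> bool:
    """True when an instance's points lie on a sphere of target-like size."""
    from canopy_pheno.calibration import fit_sphere

    pts = cloud.points[instance.point_indices]
    if len(pts) < 10:
        return False
    try:
        fit = fit_sphere(pts)
    except (ValueError, np.linalg.LinAlgError):
        return False
    return 5.0 <= fit.diameter <= 50.0 and fit.rms_residual < 0.04 * fit.radius


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    records: list[TraitRecord]
    truth: GroundTruth | None
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Artifacts: the (possibly generated) input cloud, instance summary CSV,
    trait CSV, manifest JSON, and for synthetic scenes the ground-truth
    trait and label tables. Rerunning with the same config reproduces
    byte-identical trait CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    truth: GroundTruth | None = None

    def stage(name: str, cloud: PointCloud) -> None:
        counts[name] = len(cloud)
        logger.info("%s: %d points", name, len(cloud))

    try:
        if config.scene is not None:
            spec = SceneSpec.from_dict({**config.scene, "seed": config.seed})
            cloud, truth = generate_scene(spec)
            io.write_point_cloud(cloud, out_dir / "scene.xyz")
            truth.trait_frame().to_csv(out_dir / "truth_traits.csv", index=False)
            truth.label_frame().to_csv(out_dir / "truth_labels.csv", index=False)
            expected_spacing = spec.plant_spacing
        else:
            path = Path(config.input_cloud)
            if not path.exists():
                raise FileNotFoundError(f"input cloud not found: {path}")
            cloud = io.read_point_cloud(path)
            expected_spacing = None
        stage("input", cloud)

        cloud, rep_sor = statistical_outlier_removal(
            cloud, k=config.sor_k, std_ratio=config.sor_std
        )
        stage("statistical_filter", cloud)
        cloud, rep_vox = voxel_downsample(cloud, VoxelParams(config.voxel_edge))
        stage("voxel_downsample", cloud)

        plane = ransac_plane(
            cloud,
            distance_threshold=config.ransac_threshold,
            iterations=config.ransac_iterations,
            seed=config.seed,
        )
        cloud, transform = level_scene(cloud, plane)
        leveled_plane = ransac_plane(
            cloud,
            distance_threshold=config.ransac_threshold,
            iterations=config.ransac_iterations,
            seed=config.seed,
        )
        cloud = remove_ground(cloud, leveled_plane, margin=config.ground_margin)
        stage("ground_removed", cloud)

        if config.plot_map is not None:
            cloud = assign_plots(cloud, io.read_plot_map(config.plot_map))

        instances = segment_plants(
            cloud,
            cell_size=config.cell_size,
            min_points=config.min_points,
            expected_spacing=expected_spacing,
        )
        # calibration targets segment like compact plants; drop anything that
        # fits a plausible sphere almost perfectly
        plants_only = [
            inst for inst in instances if not _is_calibration_sphere(cloud, inst)
        ]
        if len(plants_only) != len(instances):
            logger.info(
                "excluded %d sphere-like instance(s) from phenotyping",
                len(instances) - len(plants_only),
            )
        instances = plants_only
        for i, inst in enumerate(instances, start=1):
            inst.instance_id = i
        counts["instances"] = len(instances)
        logger.info("segmentation: %d instances", len(instances))
        instances_frame(instances).to_csv(out_dir / "instances.csv", index=False)

        records = [
            extract_traits(inst, cloud, ground_reference=0.0) for inst in instances
        ]
        frame = traits_frame(records)
        frame.to_csv(out_dir / "traits.csv", index=False, float_format="%.6f")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "counts": counts,
        "plane": plane.to_dict(),
        "filter_reports": {
            "statistical": dataclasses.asdict(rep_sor),
            "voxel": dataclasses.asdict(rep_vox),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(out_dir=out_dir, records=records, truth=truth, counts=counts)


def match_plants(
    records: list[TraitRecord], truth: GroundTruth, max_distance: float
) -> tuple[list[tuple[TraitRecord, int]], int]:
    """Match extracted plants to true plants by nearest stem base.

    Returns (record, true-plant-index) pairs and the number of unmatched
    true plants; each true plant is used at most once.
    """
    bases = np.array([p.base_xy for p in truth.plants])
    taken = np.zeros(len(bases), dtype=bool)
    matched = []
    for rec in records:
        d = np.linalg.norm(bases - np.array(rec.base_xy), axis=1)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_distance:
            matched.append((rec, j))
            taken[j] = True
    return matched, int((~taken).sum())


def validate_against_truth(
    result: PipelineResult,
    truth: GroundTruth | None = None,
    plant_spacing: float = 60.0,
) -> dict[str, EvalReport]:
    """Agreement statistics per trait between extracted and true values.

    Plants are matched by stem base within half the plant spacing; leaves
    within a matched plant are matched by growth height. Unmatched plants
    are excluded and counted in the log.
    """
    truth = truth if truth is not None else result.truth
    if truth is None:
        raise ValueError("no ground truth available for validation")
    if not result.records:
        raise ValueError("empty run: no extracted plants to validate")
    matched, unmatched = match_plants(result.records, truth, plant_spacing / 2.0)
    if unmatched:
        logger.warning("%d true plant(s) had no matching extraction", unmatched)

    height_pairs = ([], [])
    leaf_pairs: dict[str, tuple[list, list]] = {c: ([], []) for c in _TRAIT_COLUMNS}
    for rec, j in matched:
        plant = truth.plants[j]
        height_pairs[0].append(plant.height)
        height_pairs[1].append(rec.height_cm)
        true_leaves = list(plant.leaves)
        used = np.zeros(len(true_leaves), dtype=bool)
        for lt in rec.leaves:
            if not true_leaves:
                break
            gh = np.array([l.growth_height for l in true_leaves])
            d = np.abs(gh - lt.growth_height_cm)
            d[used] = np.inf
            k = int(np.argmin(d))
            if d[k] > 10.0:
                continue
            used[k] = True
            tl = true_leaves[k]
            for col, true_v, sys_v in [
                ("length_cm", tl.length, lt.length_cm),
                ("width_cm", tl.width, lt.width_cm),
                ("inclination_deg", tl.inclination, lt.inclination_deg),
                ("growth_height_cm", tl.growth_height, lt.growth_height_cm),
            ]:
                leaf_pairs[col][0].append(true_v)
                leaf_pairs[col][1].append(sys_v)

    reports = {
        "height_cm": evaluate_pairs(
            PairedMeasurements(
                manual=height_pairs[0], system=height_pairs[1], label="height_cm"
            )
        )
    }
    for col, (tv, sv) in leaf_pairs.items():
        if tv:
            reports[col] = evaluate_pairs(
                PairedMeasurements(manual=tv, system=sv, label=col)
            )
    return reports
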