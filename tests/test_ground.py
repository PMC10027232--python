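import numpy as np
import pytest

from canopy_pheno.cloud import PointCloud
from canopy_pheno.ground import (
    PlaneModel,
    level_scene,
    ransac_plane,
    remove_ground,
)
from canopy_pheno.synthetic import generate_scene, SceneSpec


def tilted_plane_cloud(rng, slope_deg, n_plane=1000, n_off=0, roughness=0.0):
    a = np.radians(slope_deg)
    normal = np.array([np.sin(a), 0.0, np.cos(a)])
    u = np.array([np.cos(a), 0.0, -np.sin(a)])
    v = np.array([0.0, 1.0, 0.0])
    coords = rng.uniform(-100, 100, (n_plane, 2))
    pts = coords[:, :1] * u + coords[:, 1:] * v
    if roughness:
        pts = pts + rng.normal(0, roughness, (n_plane, 1)) * normal
    if n_off:
        off = rng.uniform(-100, 100, (n_off, 2))
        h = rng.uniform(5, 80, (n_off, 1))
        pts = np.vstack([pts, off[:, :1] * u + off[:, 1:] * v + h * normal])
    return PointCloud(points=pts), normal


def test_dominant_exact_plane(rng):
    ground = np.column_stack(
        [rng.uniform(-50, 50, 1000), rng.uniform(-50, 50, 1000), np.zeros(1000)]
    )
    plants = np.column_stack(
        [rng.uniform(-50, 50, 50), rng.uniform(-50, 50, 50), rng.uniform(10, 80, 50)]
    )
    cloud = PointCloud(points=np.vstack([ground, plants]))
    plane = ransac_plane(cloud, distance_threshold=0.5, seed=0)
    np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-6)
    assert set(range(1000)) <= set(plane.inlier_indices.tolist())


def test_tilted_plane_with_outliers(rng):
    cloud, normal = tilted_plane_cloud(rng, 5.0, n_plane=800, n_off=200)
    plane = ransac_plane(cloud, distance_threshold=0.5, iterations=500, seed=42)
    angle = np.degrees(np.arccos(np.clip(plane.normal @ normal, -1, 1)))
    assert angle < 0.5


def test_plane_requires_three_points():
    with pytest.raises(ValueError, match="at least 3"):
        ransac_plane(PointCloud(points=np.zeros((2, 3))), seed=0)


def test_collinear_points_rejected():
    pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="collinear"):
        ransac_plane(PointCloud(points=pts), distance_threshold=0.1, seed=0)


def test_level_scene_identity_when_already_level(rng):
    cloud = PointCloud(points=rng.uniform(0, 10, (100, 3)))
    plane = PlaneModel(
        normal=np.array([0.0, 0.0, 1.0]),
        offset=0.0,
        inlier_indices=np.arange(100),
        inlier_rms=0.0,
    )
    leveled, tf = level_scene(cloud, plane)
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(leveled.points, cloud.points, atol=1e-12)


def test_leveling_is_rigid(rng):
    cloud, _ = tilted_plane_cloud(rng, 4.0, n_plane=200, n_off=100)
    plane = ransac_plane(cloud, seed=1)
    leveled, tf = level_scene(cloud, plane)
    assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-12)
    i, j = 3, 150
    d0 = np.linalg.norm(cloud.points[i] - cloud.points[j])
    d1 = np.linalg.norm(leveled.points[i] - leveled.points[j])
    assert d1 == pytest.approx(d0, abs=1e-9)


def test_leveling_twice_is_identity(rng):
    cloud, _ = tilted_plane_cloud(rng, 5.0, n_plane=500, n_off=100, roughness=0.1)
    plane = ransac_plane(cloud, seed=2)
    leveled, _ = level_scene(cloud, plane)
    plane2 = ransac_plane(leveled, seed=2)
    leveled2, tf2 = level_scene(leveled, plane2)
    np.testing.assert_allclose(tf2.rotation, np.eye(3), atol=1e-6)
    np.testing.assert_allclose(leveled2.points, leveled.points, atol=1e-6)


def test_leveled_ground_within_threshold(rng):
    threshold = 1.0
    cloud, _ = tilted_plane_cloud(rng, 5.0, n_plane=1000, n_off=200, roughness=0.2)
    plane = ransac_plane(cloud, distance_threshold=threshold, seed=3)
    leveled, _ = level_scene(cloud, plane)
    ground_z = leveled.points[plane.inlier_indices, 2]
    assert np.abs(ground_z).max() <= threshold + 1e-9


def test_remove_ground_margin_definition(rng):
    cloud, _ = tilted_plane_cloud(rng, 0.0, n_plane=500, n_off=300)
    plane = ransac_plane(cloud, seed=4)
    leveled, _ = level_scene(cloud, plane)
    plane_leveled = ransac_plane(leveled, seed=4)
    kept = remove_ground(leveled, plane_leveled, margin=1.0)
    assert kept.points[:, 2].min() > 1.0
    with pytest.raises(ValueError, match="margin"):
        remove_ground(leveled, plane_leveled, margin=-1.0)


def test_remove_ground_matches_truth_on_noiseless_scene(clean_scene):
    _, (cloud, truth) = clean_scene
    plane = ransac_plane(cloud, distance_threshold=0.5, seed=5)
    kept = remove_ground(cloud, plane, margin=1.0)
    removed_mask = np.ones(len(cloud), dtype=bool)
    # reconstruct mask via distances (remove_ground keeps > margin)
    removed_mask = plane.signed_distance(cloud.points) <= 1.0
    true_ground = truth.labels == 0
    tp = np.sum(removed_mask & true_ground)
    recall = tp / true_ground.sum()
    precision = tp / removed_mask.sum()
    assert recall >= 0.99
    assert precision >= 0.99
    # retained points are plant-labeled except stem bottoms inside the margin
    assert set(np.unique(truth.labels[~removed_mask])) <= set(
        range(1, len(truth.plants) + 1)
    )
    assert len(kept) == int((~removed_mask).sum())


@pytest.mark.parametrize("seed", range(5))
def test_normal_recovery_on_seeded_scenes(seed):
    spec = SceneSpec(
        rows=1,
        plants_per_row=1,
        ground_slope=float(seed) + 1.0,
        ground_roughness=0.2,
        noise_sigma=0.1,
        n_outliers=20,
        sphere_diameters=(),
        ground_density=1.0,
        margin=75.0,
        seed=seed,
    )
    cloud, truth = generate_scene(spec)
    plane = ransac_plane(cloud, distance_threshold=1.0, iterations=500, seed=seed)
    angle = np.degrees(np.arccos(np.clip(plane.normal @ truth.plane_normal, -1, 1)))
    assert angle < 1.0
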