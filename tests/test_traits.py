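import math

import numpy as np
import pytest

from canopy_pheno.cloud import PointCloud
from canopy_pheno.segmentation import PlantInstance
from canopy_pheno.synthetic import LeafSpec, PlantSpec, generate_plant
from canopy_pheno.traits import (
    LeafSegment,
    extract_leaves,
    leaf_growth_height,
    leaf_inclination,
    leaf_length,
    leaf_width,
    plant_height,
)


def whole_plant_instance(cloud):
    return PlantInstance(1, np.arange(len(cloud)), (0.0, 0.0))


# ------------------------------------------------------------------ height


def test_plant_height_is_z_extent():
    pts = np.array([[0, 0, 0.0], [1, 1, 48.56], [2, 2, 10.0]])
    cloud = PointCloud(points=pts)
    inst = whole_plant_instance(cloud)
    assert plant_height(inst, cloud) == pytest.approx(48.56)
    assert plant_height(inst, cloud, ground_reference=0.0) == pytest.approx(48.56)


def test_plant_height_on_generated_plant():
    spec = PlantSpec(base_xy=(0, 0), height=80.0)
    cloud = generate_plant(spec, density=4.0)
    assert plant_height(whole_plant_instance(cloud), cloud) == pytest.approx(
        80.0, abs=0.5
    )


def test_single_point_height_warns():
    cloud = PointCloud(points=np.array([[0, 0, 5.0]]))
    with pytest.warns(UserWarning, match="single-point"):
        h = plant_height(whole_plant_instance(cloud), cloud)
    assert h == 0.0


def test_empty_instance_rejected():
    cloud = PointCloud(points=np.array([[0, 0, 5.0]]))
    with pytest.raises(ValueError, match="empty"):
        plant_height(PlantInstance(1, np.array([], int), (0, 0)), cloud)


@pytest.mark.parametrize("angle", [30.0, 123.0, 270.0])
def test_plant_height_invariant_under_z_rotation_and_xy_shift(angle):
    spec = PlantSpec(
        base_xy=(0, 0), height=70.0,
        leaves=[LeafSpec(growth_height=30, azimuth=10, length=25, width=4,
                         inclination=30)],
    )
    cloud = generate_plant(spec)
    h0 = plant_height(whole_plant_instance(cloud), cloud)
    a = math.radians(angle)
    R = np.array([[math.cos(a), -math.sin(a), 0],
                  [math.sin(a), math.cos(a), 0],
                  [0, 0, 1.0]])
    moved = PointCloud(points=cloud.points @ R.T + np.array([11.0, -7.0, 0.0]))
    assert plant_height(whole_plant_instance(moved), moved) == pytest.approx(
        h0, abs=1e-9
    )


# ------------------------------------------------------------------ leaves


def three_leaf_plant():
    leaves = [
        LeafSpec(growth_height=25, azimuth=0, length=28, width=5, inclination=35,
                 arch=0.2),
        LeafSpec(growth_height=40, azimuth=140, length=25, width=4, inclination=25,
                 arch=0.15),
        LeafSpec(growth_height=55, azimuth=260, length=22, width=4, inclination=40,
                 arch=0.1),
    ]
    return PlantSpec(base_xy=(0, 0), height=90.0, leaves=leaves)


def test_extract_three_leaves_match_truth_labels():
    spec = three_leaf_plant()
    cloud = generate_plant(spec, density=4.0)
    segments = extract_leaves(whole_plant_instance(cloud), cloud)
    assert len(segments) == 3
    for seg in segments:
        true_parts = cloud.labels[seg.point_indices]
        # each segment is pure: all its points belong to one true leaf
        assert len(set(true_parts)) == 1
        assert set(true_parts) <= {1, 2, 3}
    # and covers nearly all of that leaf's off-stem points
    for k, seg in zip((1, 2, 3), sorted(segments, key=lambda s: s.attachment[2])):
        n_true = int((cloud.labels == k).sum())
        assert seg.point_indices.size > 0.7 * n_true


def test_leafless_stem_gives_empty_list():
    cloud = generate_plant(PlantSpec(base_xy=(0, 0), height=60.0))
    assert extract_leaves(whole_plant_instance(cloud), cloud) == []


def test_opposite_leaves_at_same_height_split_azimuthally():
    leaves = [
        LeafSpec(growth_height=30, azimuth=0, length=25, width=4, inclination=30),
        LeafSpec(growth_height=30, azimuth=180, length=25, width=4, inclination=30),
    ]
    cloud = generate_plant(PlantSpec(base_xy=(0, 0), height=80.0, leaves=leaves))
    segments = extract_leaves(whole_plant_instance(cloud), cloud)
    assert len(segments) == 2


# ------------------------------------------------------------------ metrics


def straight_segment(length=30.0, n=31, incl_deg=0.0):
    t = np.linspace(0, length, n)
    a = math.radians(incl_deg)
    mid = np.column_stack([t * math.cos(a), np.zeros(n), 40.0 + t * math.sin(a)])
    return LeafSegment(point_indices=np.arange(n), midrib=mid, attachment=mid[0])


def test_leaf_length_straight_line():
    assert leaf_length(straight_segment(30.0)) == pytest.approx(30.0)


def test_leaf_length_quarter_circle():
    r = 20.0
    t = np.linspace(0, math.pi / 2, 100)
    mid = np.column_stack([r * np.sin(t), np.zeros(100), r - r * np.cos(t)])
    seg = LeafSegment(point_indices=np.arange(100), midrib=mid, attachment=mid[0])
    assert leaf_length(seg) == pytest.approx(math.pi / 2 * r, rel=1e-3)


def test_arc_length_at_least_chord():
    for arch in (0.0, 0.1, 0.3):
        leaf = LeafSpec(growth_height=30, azimuth=0, length=28, width=5,
                        inclination=30, arch=arch)
        cloud = generate_plant(PlantSpec(base_xy=(0, 0), height=80, leaves=[leaf]))
        seg = extract_leaves(whole_plant_instance(cloud), cloud)[0]
        chord = np.linalg.norm(seg.midrib[-1] - seg.attachment)
        assert leaf_length(seg) >= chord - 1e-9


def test_leaf_width_flat_strip():
    xs = np.linspace(0, 30, 61)
    ys = np.linspace(-2.5, 2.5, 11)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, 40.0)])
    cloud = PointCloud(points=pts)
    n = 30
    mid = np.column_stack([np.linspace(0, 30, n), np.zeros(n), np.full(n, 40.0)])
    seg = LeafSegment(point_indices=np.arange(len(pts)), midrib=mid, attachment=mid[0])
    assert leaf_width(seg, cloud) == pytest.approx(5.0, abs=0.3)


def test_leaf_width_two_points_rejected():
    cloud = PointCloud(points=np.array([[0, 0, 0.0], [1, 0, 0.0]]))
    seg = straight_segment(n=2)
    seg.point_indices = np.array([0, 1])
    with pytest.raises(ValueError):
        leaf_width(seg, cloud)


def test_inclination_definitions():
    # horizontal base tangent, vertical stem: stem-leaf angle 90, theta 0
    assert leaf_inclination(straight_segment(incl_deg=0.0)) == pytest.approx(
        0.0, abs=1e-6
    )
    assert leaf_inclination(straight_segment(incl_deg=45.0)) == pytest.approx(
        45.0, abs=1e-6
    )


def test_growth_height_is_attachment_z():
    assert leaf_growth_height(straight_segment()) == pytest.approx(40.0)


def test_growth_height_below_ground_warns():
    seg = straight_segment()
    seg.attachment = seg.attachment.copy()
    seg.attachment[2] = -3.0
    with pytest.warns(UserWarning, match="below ground"):
        assert leaf_growth_height(seg) == pytest.approx(-3.0)
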