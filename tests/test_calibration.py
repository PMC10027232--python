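import numpy as np
import pytest
from scipy.optimize import least_squares

from canopy_pheno.calibration import (
    Correspondence,
    DLTModel,
    apply_scale,
    calibrate_scale,
    fit_sphere,
    project_dlt,
    solve_dlt,
)
from canopy_pheno.cloud import PointCloud


def sphere_points(center, radius, n, rng, hemisphere=False):
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    if hemisphere:
        d[:, 2] = np.abs(d[:, 2])
    return np.asarray(center) + radius * d


def pinhole_correspondences(rng, n=8):
    """Forward-project random 3D points through a random pinhole camera."""
    obj = rng.uniform(-1, 1, size=(n, 3))
    f = rng.uniform(500, 1500)
    K = np.array([[f, 0, rng.uniform(200, 600)], [0, f, rng.uniform(200, 600)], [0, 0, 1]])
    A = rng.normal(size=(3, 3))
    R = np.linalg.qr(A)[0]
    if np.linalg.det(R) < 0:
        R = -R
    t = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(4, 8)])
    cam = (obj @ R.T + t) @ K.T
    img = cam[:, :2] / cam[:, 2:]
    return [Correspondence(tuple(i), tuple(o)) for i, o in zip(img, obj)], obj, img


# ------------------------------------------------------------------ spheres


def test_sphere_fit_exact_on_noiseless_sample(rng):
    pts = sphere_points([3.0, -2.0, 7.0], 12.5, 200, rng)
    fit = fit_sphere(pts)
    assert fit.radius == pytest.approx(12.5, abs=1e-6)
    assert fit.rms_residual < 1e-9
    np.testing.assert_allclose(fit.center, [3.0, -2.0, 7.0], atol=1e-6)


def test_sphere_fit_hemisphere_with_noise_matches_geometric_oracle(rng):
    truth_c, truth_r = np.array([0.0, 0.0, 0.0]), 10.0
    pts = sphere_points(truth_c, truth_r, 500, rng, hemisphere=True)
    pts = pts + rng.normal(0, 0.1, pts.shape)
    fit = fit_sphere(pts)
    assert fit.radius == pytest.approx(truth_r, abs=0.1)

    # independent oracle: scipy least_squares on the geometric distance
    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    oracle = least_squares(resid, x0=np.array([0.1, -0.1, 0.2, 9.0])).x
    assert fit.radius == pytest.approx(oracle[3], abs=1e-6)
    np.testing.assert_allclose(fit.center, oracle[:3], atol=1e-6)


def test_sphere_fit_insufficient_points():
    with pytest.raises(ValueError, match="insufficient"):
        fit_sphere(np.eye(3))


def test_sphere_fit_coplanar_points_rejected():
    pts = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)])
    with pytest.raises(ValueError):
        fit_sphere(pts)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sphere_fit_rigid_equivariance(seed):
    rng = np.random.default_rng(seed)
    pts = sphere_points([1.0, 2.0, 3.0], 5.0, 300, rng)
    fit = fit_sphere(pts)
    A = rng.normal(size=(3, 3))
    R = np.linalg.qr(A)[0]
    if np.linalg.det(R) < 0:
        R = -R
    t = rng.uniform(-50, 50, 3)
    fit2 = fit_sphere(pts @ R.T + t)
    assert fit2.radius == pytest.approx(fit.radius, abs=1e-9)
    np.testing.assert_allclose(fit2.center, R @ fit.center + t, atol=1e-8)


# ------------------------------------------------------------------ scale


def test_scale_identity_and_ratio():
    assert calibrate_scale([25.0, 20.0], [25.0, 20.0]).scale == pytest.approx(1.0)
    cal = calibrate_scale([24.0, 19.2], [25.0, 20.0])
    assert cal.scale == pytest.approx(25.0 / 24.0, rel=1e-12)
    assert cal.scale == pytest.approx(20.0 / 19.2, rel=1e-12)


def test_scale_errors():
    with pytest.raises(ValueError, match="at least one"):
        calibrate_scale([], [])
    with pytest.raises(ValueError, match="length"):
        calibrate_scale([25.0], [25.0, 20.0])
    with pytest.raises(ValueError, match="non-positive"):
        calibrate_scale([-1.0], [25.0])


def test_scale_equivariance(rng):
    fitted = list(rng.uniform(10, 30, 4))
    known = list(rng.uniform(10, 30, 4))
    s = 1.7
    a = calibrate_scale(fitted, known).scale
    b = calibrate_scale([s * f for f in fitted], known).scale
    assert b == pytest.approx(a / s, rel=1e-12)


def test_apply_scale_keeps_centroid(rng):
    cloud = PointCloud(points=rng.uniform(-10, 10, (100, 3)))
    cal = calibrate_scale([24.0], [25.0])
    scaled = apply_scale(cloud, cal)
    np.testing.assert_allclose(
        scaled.points.mean(axis=0), cloud.points.mean(axis=0), atol=1e-10
    )
    d0 = np.linalg.norm(cloud.points[0] - cloud.points[1])
    d1 = np.linalg.norm(scaled.points[0] - scaled.points[1])
    assert d1 == pytest.approx(cal.scale * d0, rel=1e-12)


# ------------------------------------------------------------------ DLT


@pytest.mark.parametrize("seed", range(20))
def test_dlt_noiseless_reprojection(seed):
    rng = np.random.default_rng(seed)
    cors, obj, img = pinhole_correspondences(rng, n=10)
    model = solve_dlt(cors)
    assert model.reprojection_rms < 1e-8
    proj = project_dlt(model, obj)
    np.testing.assert_allclose(proj, img, atol=1e-7)


def test_dlt_too_few_correspondences(rng):
    cors, _, _ = pinhole_correspondences(rng, n=8)
    with pytest.raises(ValueError, match="at least 6"):
        solve_dlt(cors[:5])


def test_dlt_coplanar_rejected(rng):
    obj = np.column_stack([rng.uniform(-1, 1, (10, 2)), np.zeros(10)])
    cors = [Correspondence((x * 100, y * 100), tuple(o)) for (x, y, _), o in zip(obj, obj)]
    with pytest.raises(ValueError, match="coplanar"):
        solve_dlt(cors)


def test_dlt_constant_projection():
    params = np.zeros(11)
    params[3], params[7] = -5.0, -7.0
    model = DLTModel(params=params, reprojection_rms=0.0)
    np.testing.assert_allclose(project_dlt(model, [3.0, 1.0, -2.0]), [5.0, 7.0])


def test_dlt_vanishing_denominator():
    params = np.zeros(11)
    params[8] = 1.0  # l9 = 1 -> denominator X + 1
    model = DLTModel(params=params, reprojection_rms=0.0)
    with pytest.raises(ValueError, match="denominator"):
        project_dlt(model, [-1.0, 0.0, 0.0])


def test_dlt_json_round_trip(rng):
    cors, _, _ = pinhole_correspondences(rng)
    model = solve_dlt(cors)
    back = DLTModel.from_json(model.to_json())
    np.testing.assert_allclose(back.params, model.params)
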