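import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scalpmap import (
    AffineTransform,
    CoherentPointDrift,
    CPDParams,
    DegenerateGeometryError,
    DownsampleParams,
    IterativeClosestPoint,
    LandmarkSet,
    NonrigidWarp,
    RigidTransform,
    affine_from_landmarks,
    apply_transform,
    compose,
    downsample_grid,
    register_surface_to_atlas,
    rigid_from_landmarks,
)

FIVE = LandmarkSet(
    {
        "nasion": (0.0, 95.0, 2.0),
        "inion": (1.0, -98.0, 5.0),
        "Cz": (0.0, -3.0, 112.0),
        "LPA": (-72.0, -8.0, 1.0),
        "RPA": (71.0, -6.0, -2.0),
    }
)


def random_rigid(rng) -> RigidTransform:
    return RigidTransform(
        Rotation.random(random_state=rng).as_matrix(), rng.uniform(-30, 30, 3)
    )


# ---------------------------------------------------------------------------
# landmark fits
# ---------------------------------------------------------------------------


def test_rigid_fit_recovers_planted_transform(rng):
    for _ in range(5):
        t = random_rigid(rng)
        dst = FIVE.transformed(t.apply)
        fit = rigid_from_landmarks(FIVE, dst)
        np.testing.assert_allclose(fit.rotation, t.rotation, atol=1e-9)
        np.testing.assert_allclose(fit.translation, t.translation, atol=1e-9)
    ident = rigid_from_landmarks(FIVE, FIVE)
    np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)


def test_rigid_fit_never_returns_reflection():
    mirrored = FIVE.transformed(lambda p: p * np.array([-1.0, 1.0, 1.0]))
    fit = rigid_from_landmarks(FIVE, mirrored)
    assert np.linalg.det(fit.rotation) == pytest.approx(1.0)
    resid = np.linalg.norm(fit.apply(FIVE.array(("nasion", "Cz", "LPA", "RPA"))) -
                           mirrored.array(("nasion", "Cz", "LPA", "RPA")))
    assert resid > 1.0


def test_rigid_fit_errors():
    with pytest.raises(ValueError, match="missing"):
        rigid_from_landmarks(LandmarkSet({"nasion": (0, 1, 0)}), FIVE)
    line = LandmarkSet(
        {"nasion": (0.0, 0, 0), "Cz": (1.0, 0, 0), "LPA": (2.0, 0, 0), "RPA": (3.0, 0, 0)}
    )
    with pytest.raises(DegenerateGeometryError):
        rigid_from_landmarks(line, line)


def test_affine_fit_recovers_scale_and_shear(rng):
    lin = np.array([[1.08, 0.06, 0.0], [0.02, 0.93, 0.05], [-0.01, 0.03, 1.04]])
    planted = AffineTransform(lin, np.array([4.0, -6.0, 11.0]))
    dst = FIVE.transformed(planted.apply)
    fit = affine_from_landmarks(FIVE, dst)
    np.testing.assert_allclose(fit.linear, planted.linear, atol=1e-9)
    np.testing.assert_allclose(fit.translation, planted.translation, atol=1e-9)
    ident = affine_from_landmarks(FIVE, FIVE)
    np.testing.assert_allclose(ident.linear, np.eye(3), atol=1e-9)


def test_affine_fit_rejects_coplanar_landmarks():
    flat = LandmarkSet(
        {
            "nasion": (0.0, 95.0, 0.0),
            "inion": (0.0, -98.0, 0.0),
            "Cz": (5.0, 0.0, 0.0),
            "LPA": (-72.0, 0.0, 0.0),
            "RPA": (71.0, 0.0, 0.0),
        }
    )
    with pytest.raises(DegenerateGeometryError):
        affine_from_landmarks(flat, flat)


def test_landmark_fit_residual_grows_with_noise(rng):
    t = random_rigid(rng)
    dst_clean = FIVE.transformed(t.apply)
    names = ("nasion", "inion", "Cz", "LPA", "RPA")
    resids = []
    for sigma in (0.0, 1.0, 4.0):
        noisy = LandmarkSet(
            {n: dst_clean[n] + rng.normal(0, sigma, 3) for n in names}
        )
        fit = rigid_from_landmarks(FIVE, noisy, names)
        resids.append(np.linalg.norm(fit.apply(FIVE.array(names)) - noisy.array(names)))
    assert resids[0] < 1e-9 and resids[0] < resids[1] < resids[2]


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def test_icp_self_registration_is_identity(rng):
    pts = rng.uniform(-50, 50, (200, 3))
    res = IterativeClosestPoint(pts, pts).fit()
    np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(res.transform.translation, 0, atol=1e-12)
    assert res.converged and res.final_mean_distance_mm == pytest.approx(0.0)


def test_icp_recovers_small_rigid_displacement(rng):
    pts = rng.uniform(-80, 80, (400, 3))
    t = RigidTransform(
        Rotation.from_euler("z", 5, degrees=True).as_matrix(), np.array([3.0, 0, -1.0])
    )
    res = IterativeClosestPoint(pts, t.apply(pts)).fit()
    assert res.final_mean_distance_mm < 0.01


def test_icp_mean_distance_non_increasing(rng):
    for _ in range(10):
        pts = rng.uniform(-60, 60, (150, 3))
        t = random_rigid(rng)
        res = IterativeClosestPoint(pts, t.apply(pts)).fit()
        diffs = np.diff(res.mean_distances)
        assert (diffs <= 1e-12).all()


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def test_compose_matches_sequential_application(rng):
    pts = rng.uniform(-10, 10, (20, 3))
    rigid = random_rigid(rng)
    aff = AffineTransform(np.eye(3) + rng.uniform(-0.1, 0.1, (3, 3)), rng.uniform(-5, 5, 3))
    np.testing.assert_allclose(
        compose(rigid, aff).apply(pts), aff.apply(rigid.apply(pts)), atol=1e-10
    )
    np.testing.assert_allclose(
        compose(rigid, rigid).apply(pts), rigid.apply(rigid.apply(pts)), atol=1e-10
    )


def test_identity_and_zero_weight_warp(rng):
    pts = rng.uniform(-10, 10, (15, 3))
    np.testing.assert_array_equal(apply_transform(RigidTransform.identity(), pts), pts)
    warp = NonrigidWarp(pts[:5], kernel_width=4.0, weights=np.zeros((5, 3)))
    np.testing.assert_array_equal(apply_transform(warp, pts), pts)


# ---------------------------------------------------------------------------
# CPD
# ---------------------------------------------------------------------------


def head_sample(head_coarse, n=500, seed=0):
    mesh, _, _ = head_coarse
    rng = np.random.default_rng(seed)
    return mesh.vertices[rng.choice(mesh.n_vertices, n, replace=False)]


@pytest.mark.parametrize("mode", ["affine", "nonrigid"])
def test_cpd_self_registration_near_identity(head_coarse, mode):
    pts = head_sample(head_coarse, 300)
    res = CoherentPointDrift(pts, pts, mode, CPDParams(omega=0.0)).fit()
    moved = res.transform.apply(pts)
    # in normalized units the fitted map deviates from identity by < 1e-3
    scale = np.sqrt(((pts - pts.mean(0)) ** 2).sum(1).mean())
    assert np.linalg.norm(moved - pts, axis=1).max() / scale < 1e-3


def test_cpd_affine_recovers_planted_transform(head_coarse):
    pts = head_sample(head_coarse, 600)
    lin = np.array([[1.06, 0.05, -0.01], [0.03, 0.95, 0.02], [0.0, -0.04, 1.05]])
    planted = AffineTransform(lin, np.array([8.0, -5.0, 3.0]))
    res = CoherentPointDrift(pts, planted.apply(pts), "affine", CPDParams(omega=0.1)).fit()
    probe = head_sample(head_coarse, 100, seed=1)
    err = np.linalg.norm(res.transform.apply(probe) - planted.apply(probe), axis=1)
    assert np.median(err) < 0.5


def test_cpd_objective_non_increasing_and_nonrigid_beats_rigid(head_coarse):
    pts = head_sample(head_coarse, 400)
    rng = np.random.default_rng(7)
    centers = pts[rng.choice(len(pts), 8, replace=False)]
    dirs = rng.normal(size=(8, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    warp = NonrigidWarp(centers, kernel_width=40.0, weights=dirs * 4.0)
    fixed = warp.apply(pts)
    res = CoherentPointDrift(pts, fixed, "nonrigid", CPDParams()).fit()
    obj = np.array(res.objective_history)
    assert (np.diff(obj) <= 1e-6 * np.abs(obj[:-1]) + 1e-6).all()
    from scipy.spatial import cKDTree

    tree = cKDTree(fixed)
    resid_rigid = tree.query(pts)[0].mean()
    resid_cpd = tree.query(res.transform.apply(pts))[0].mean()
    assert resid_cpd < resid_rigid


def test_cpd_invariant_under_common_rigid(head_coarse, rng):
    pts = head_sample(head_coarse, 300)
    lin = np.eye(3) * 1.04
    planted = AffineTransform(lin, np.array([2.0, 1.0, -3.0]))
    fixed = planted.apply(pts)
    base = CoherentPointDrift(pts, fixed, "affine", CPDParams(omega=0.0)).fit()
    common = random_rigid(rng)
    moved = CoherentPointDrift(
        common.apply(pts), common.apply(fixed), "affine", CPDParams(omega=0.0)
    ).fit()
    probe = head_sample(head_coarse, 50, seed=2)
    np.testing.assert_allclose(
        moved.transform.apply(common.apply(probe)),
        common.apply(base.transform.apply(probe)),
        atol=1e-3,
    )


def test_cpd_input_validation():
    with pytest.raises(ValueError):
        CoherentPointDrift(np.zeros((3, 3)), np.zeros((10, 3)))
    with pytest.raises(ValueError):
        CoherentPointDrift(np.zeros((10, 3)), np.zeros((10, 3)), mode="rigid")
    with pytest.raises(ValueError):
        CPDParams(omega=1.0)


# ---------------------------------------------------------------------------
# surface-to-atlas pipeline
# ---------------------------------------------------------------------------


def test_register_identity_subject(head_coarse):
    from scalpmap import nearest_node

    mesh, lm, sensors = head_coarse
    expected = np.stack(
        [mesh.vertices[i] for i, _ in nearest_node(mesh, sensors.positions)]
    )
    # landmark affine is exactly the identity: projection matches exactly
    mapped = register_surface_to_atlas(mesh, lm, mesh, lm, sensors, method="landmarks")
    np.testing.assert_allclose(mapped.positions, expected, atol=1e-9)
    # CPD self-registration deviates by at most nearest-node quantization
    mapped = register_surface_to_atlas(
        mesh, lm, mesh, lm, sensors, method="cpd_affine", dp=DownsampleParams(800)
    )
    dev = np.linalg.norm(mapped.positions - sensors.positions, axis=1)
    assert dev.max() < 1.5 * mesh.mean_edge_length()


def test_register_missing_inion_names_landmark(head_coarse):
    mesh, lm, sensors = head_coarse
    partial = LandmarkSet({n: lm[n] for n in ("nasion", "Cz", "LPA", "RPA")})
    with pytest.raises(Exception, match="inion"):
        register_surface_to_atlas(mesh, partial, mesh, lm, sensors, method="landmarks")
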