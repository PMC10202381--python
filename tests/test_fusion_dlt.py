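import math

import numpy as np
import pytest

from maizefusion import (
    Correspondence,
    DegenerateGeometryError,
    FieldConfig,
    InsufficientCorrespondencesError,
    ValidationError,
    estimate_dlt,
    generate_field,
    match_features,
    project_cloud,
    register_cloud,
)
from maizefusion.fusion_dlt import build_dlt_system, solve_normal_equations
from maizefusion.ortho_features import FeatureSet


def projective_camera(rng=None):
    """A mildly perspective 11-coefficient camera (literal sign convention)."""
    L = np.array([1.0, 0.1, -0.2, 0.3, 0.05, -1.1, 0.15, -0.4,
                  0.02, -0.03, 0.05])
    if rng is not None:
        L = L + rng.normal(0, 0.02, 11)
    return L


def project_with(L, X):
    den = X @ L[8:11] + 1.0
    return np.column_stack([-(X @ L[:3] + L[3]) / den,
                            -(X @ L[4:7] + L[7]) / den])


def exact_correspondences(n, rng, L=None):
    L = projective_camera() if L is None else L
    X = rng.uniform(-1, 1, size=(n, 3))
    xy = project_with(L, X)
    return [Correspondence(xy[i], X[i]) for i in range(n)], L, X


class TestEstimateDLT:
    def test_five_pairs_insufficient(self, rng):
        corrs, _, _ = exact_correspondences(5, rng)
        with pytest.raises(InsufficientCorrespondencesError) as exc:
            estimate_dlt(corrs, min_matches=6)
        assert exc.value.needed == 6 and exc.value.given == 5

    def test_six_exact_pairs_solve(self, rng):
        corrs, L, _ = exact_correspondences(6, rng)
        model = estimate_dlt(corrs, min_matches=6)
        assert model.rms_reprojection <= 1e-8

    def test_operational_gate_default_twelve(self, rng):
        corrs, _, _ = exact_correspondences(11, rng)
        with pytest.raises(InsufficientCorrespondencesError):
            estimate_dlt(corrs)
        corrs, _, _ = exact_correspondences(12, rng)
        estimate_dlt(corrs)  # no raise

    def test_twenty_exact_pairs_recover_camera(self, rng):
        corrs, L, X = exact_correspondences(20, rng)
        model = estimate_dlt(corrs)
        assert model.rms_reprojection <= 1e-8
        np.testing.assert_allclose(model.L, L, atol=1e-9)

    def test_orthographic_identity_zero_denominator_terms(self, rng):
        X = rng.uniform(-1, 1, size=(30, 3))
        corrs = [Correspondence(-X[i, :2], X[i]) for i in range(30)]
        model = estimate_dlt(corrs)
        assert np.abs(model.L[8:]).max() <= 1e-9

    def test_residual_identity_literal(self, rng):
        corrs, _, _ = exact_correspondences(15, rng)
        for c in corrs[:5]:
            c.image_xy = c.image_xy + rng.normal(0, 0.01, 2)
        model = estimate_dlt(corrs)
        np.testing.assert_array_equal(model.V, model.B @ model.L - model.W)

    def test_stable_solver_matches_normal_equations(self, rng):
        corrs, _, _ = exact_correspondences(25, rng)
        for c in corrs:
            c.image_xy = c.image_xy + rng.normal(0, 0.005, 2)
            c.weight = float(rng.uniform(0.5, 2.0))
        model = estimate_dlt(corrs)
        L_ne = solve_normal_equations(model.B, model.W, model.P)
        rel = np.linalg.norm(model.L - L_ne) / np.linalg.norm(L_ne)
        assert rel <= 1e-8

    def test_coplanar_geometry_degenerate(self, rng):
        X = rng.uniform(-1, 1, size=(20, 3))
        X[:, 2] = 0.7  # constant height: Z column proportional to 1
        xy = project_with(projective_camera(), X)
        corrs = [Correspondence(xy[i], X[i]) for i in range(20)]
        with pytest.raises(DegenerateGeometryError):
            estimate_dlt(corrs)

    def test_near_orthographic_affine_fallback_flagged(self, rng):
        # huge condition number via tiny coordinate spread at large offset
        X = rng.uniform(-1, 1, size=(20, 3))
        L = np.zeros(11)
        L[:8] = [1, 0, 0, 0, 0, 1, 0, 0]
        xy = project_with(L, X)
        corrs = [Correspondence(xy[i], X[i]) for i in range(20)]
        model = estimate_dlt(corrs, condition_threshold=1.0)
        assert model.degenerate_geometry
        assert np.all(model.L[8:] == 0)
        assert model.rms_reprojection <= 1e-8

    def test_noise_monotonicity(self, rng):
        corrs, L, X = exact_correspondences(40, rng)
        noise = rng.normal(size=(40, 2))
        last = -1.0
        for sigma in [0.0, 1e-4, 1e-3, 1e-2, 1e-1]:
            noisy = [Correspondence(c.image_xy + sigma * noise[i], c.cloud_xyz)
                     for i, c in enumerate(corrs)]
            rms = estimate_dlt(noisy).rms_reprojection
            assert rms >= last - 1e-12
            last = rms

    def test_parameter_recovery_holdout_sweep(self):
        rng = np.random.default_rng(123)
        sigma = 1e-3
        for _ in range(100):
            L = projective_camera(rng)
            X = rng.uniform(-1, 1, size=(30, 3))
            xy = project_with(L, X) + rng.normal(0, sigma, size=(30, 2))
            corrs = [Correspondence(xy[i], X[i]) for i in range(20)]
            model = estimate_dlt(corrs)
            held = project_with(L, X[20:])
            pred = model.project(X[20:])
            err = np.linalg.norm(pred - held, axis=1).mean()
            assert err <= 10 * sigma

    def test_build_system_shape(self, rng):
        corrs, _, _ = exact_correspondences(7, rng)
        B, W, P = build_dlt_system(corrs)
        assert B.shape == (14, 11) and W.shape == (14,) and P.shape == (14,)


class TestProjectCloud:
    def test_single_plant_keypoint_z_in_range(self):
        cfg = FieldConfig(n_rows=1, plants_per_row=1, growth_stage=0.5,
                          point_density=2000, seed=3)
        scene = generate_field(cfg)
        _, feats = project_cloud(scene.cloud, 0.005)
        cents = feats.of_kind("centroid")
        assert len(cents) >= 1
        z = cents.cloud_xyz[:, 2]
        lo, hi = scene.cloud.points[:, 2].min(), scene.cloud.points[:, 2].max()
        assert np.all((z >= lo) & (z <= hi))

    def test_two_identical_plants_spacing_preserved(self):
        from maizefusion import PointCloud

        cfg = FieldConfig(n_rows=1, plants_per_row=1, growth_stage=0.4,
                          point_density=2500, seed=3)
        scene = generate_field(cfg)
        plant = scene.cloud.points[scene.cloud.labels["plant_id"] == 0]
        colors = scene.cloud.colors[scene.cloud.labels["plant_id"] == 0]
        clone = plant + [0.6, 0.0, 0.0]
        cloud = PointCloud(points=np.vstack([plant, clone]),
                           colors=np.vstack([colors, colors]))
        gsd = 0.005
        _, feats = project_cloud(cloud, gsd, min_component_px=100)
        cents = feats.of_kind("centroid").keypoints
        assert len(cents) == 2
        d = np.linalg.norm(cents[0] - cents[1])
        assert abs(d - 0.6) <= gsd

    def test_self_match_zero_distance(self, small_field):
        _, feats = project_cloud(small_field.cloud, 0.005)
        cm = feats.of_kind("centroid", "marker")
        pairs = match_features(cm, cm, max_dist=0.01)
        assert len(pairs) == len(cm)
        for c in pairs:
            np.testing.assert_allclose(c.image_xy, c.cloud_xyz[:2], atol=1e-12)

    def test_empty_cloud_rejected(self):
        from maizefusion import PointCloud

        with pytest.raises(ValidationError):
            project_cloud(PointCloud(points=np.empty((0, 3))), 0.01)


class TestMatchFeatures:
    def make_sets(self, pts):
        kinds = np.array(["centroid"] * len(pts), dtype=object)
        img = FeatureSet(keypoints=pts, kinds=kinds)
        cld = FeatureSet(keypoints=pts, kinds=kinds, source="cloud_projection",
                         cloud_xyz=np.column_stack([pts, np.zeros(len(pts))]))
        return img, cld

    def test_identical_sets_perfect_pairing(self, rng):
        pts = rng.uniform(0, 1, size=(10, 2))
        img, cld = self.make_sets(pts)
        pairs = match_features(img, cld, max_dist=0.05)
        assert len(pairs) == 10

    def test_constructed_shift_within_radius(self, rng):
        pts = np.column_stack([np.arange(8) * 0.3, np.zeros(8)])
        img, _ = self.make_sets(pts)
        _, cld = self.make_sets(pts + [0.05, 0.0])
        pairs = match_features(img, cld, max_dist=0.1)
        assert len(pairs) == 8

    def test_threshold_excludes_all(self, rng):
        pts = rng.uniform(0, 1, size=(5, 2))
        img, _ = self.make_sets(pts)
        _, cld = self.make_sets(pts + 0.5)
        assert match_features(img, cld, max_dist=0.01) == []


class TestRegisterCloud:
    def test_identity_when_already_in_frame(self, rng):
        # flat ground plane at z=0 plus canopy points; image frame == cloud frame
        ground = np.column_stack([rng.uniform(0, 2, 300), rng.uniform(0, 2, 300),
                                  np.zeros(300)])
        canopy = rng.uniform(0.2, 1.0, size=(40, 3))
        pts = np.vstack([ground, canopy])
        from maizefusion import PointCloud

        cloud = PointCloud(points=pts)
        corrs = [Correspondence(canopy[i, :2], canopy[i]) for i in range(20)]
        corrs = [Correspondence(-c.image_xy, c.cloud_xyz) for c in corrs]
        # literal signs: x = -(X) for identity-like affine camera
        model = estimate_dlt([Correspondence(c.cloud_xyz[:2], c.cloud_xyz)
                              for c in corrs])
        reg, transform = register_cloud(cloud, model, reference_ground_z=0.0)
        assert abs(transform.rotation) <= 1e-6
        assert abs(transform.scale - 1.0) <= 1e-6
        np.testing.assert_allclose(transform.translation, 0, atol=1e-6)

    def test_rms_gate_refuses(self, rng):
        corrs, _, _ = exact_correspondences(15, rng)
        noisy = [Correspondence(c.image_xy + rng.normal(0, 0.2, 2), c.cloud_xyz)
                 for c in corrs]
        model = estimate_dlt(noisy)
        from maizefusion import PointCloud, RegistrationQualityError

        cloud = PointCloud(points=rng.normal(size=(50, 3)))
        with pytest.raises(RegistrationQualityError):
            register_cloud(cloud, model, rms_threshold=1e-4)
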