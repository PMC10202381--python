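import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maizefusion import (
    FieldConfig,
    PointCloud,
    TraitTable,
    ValidationError,
    crown_size,
    evaluate,
    generate_field,
    leaf_angles,
    leaf_length,
    plant_height,
    regression_metrics,
)
from maizefusion.traits_metrics import wrapped_difference


class TestPlantHeight:
    def test_two_point_closed_form(self):
        cloud = PointCloud(points=np.array([[0, 0, 0.0], [0, 0, 1.5]]))
        assert plant_height(cloud, ground_level=0.0, percentile=100) == 1.5

    def test_outlier_robust_percentile(self, rng):
        pts = np.column_stack([rng.normal(0, 0.05, 300),
                               rng.normal(0, 0.05, 300),
                               rng.uniform(0, 1.0, 300)])
        clean = plant_height(PointCloud(points=pts), percentile=99)
        spiked = np.vstack([pts, [[0, 0, 10.0]]])
        assert plant_height(PointCloud(points=spiked), percentile=99) \
            <= clean + 0.05
        assert plant_height(PointCloud(points=spiked), percentile=100) > 9.0

    def test_recovery_over_seeded_plants(self):
        from maizefusion.ground_filter import csf_ground, extract_ground, remove_ground
        from maizefusion.traits_metrics import local_ground_function

        for seed in (7, 8):
            cfg = FieldConfig(n_rows=2, plants_per_row=5, growth_stage=0.5,
                              point_density=3000, seed=seed)
            scene = generate_field(cfg)
            cls = csf_ground(scene.cloud)
            canopy = remove_ground(scene.cloud, cls)
            gl = local_ground_function(extract_ground(scene.cloud, cls))
            for pid, (x, y) in scene.plant_positions.items():
                plant = canopy.select(canopy.labels["plant_id"] == pid)
                est = plant_height(plant, ground_level=gl(x, y))
                true = scene.traits.data.query(
                    "plant_id == @pid and trait_name == 'plant_height'"
                )["value"].iloc[0]
                assert abs(est - true) <= max(0.02, 0.02 * true)

    def test_empty_plant_rejected(self):
        with pytest.raises(ValidationError):
            plant_height(PointCloud(points=np.empty((0, 3))))


class TestLeafAngles:
    def test_diagonal_chord(self):
        pts = np.array([[t, 0, t] for t in np.linspace(0, 1, 10)])
        inc, azi = leaf_angles(PointCloud(points=pts), (0.0, 0.0))
        assert inc == pytest.approx(45.0, abs=1e-9)
        assert azi == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_north_chord(self):
        pts = np.array([[0, t, 0] for t in np.linspace(0, 1, 10)])
        inc, azi = leaf_angles(PointCloud(points=pts), (0.0, 0.0))
        assert inc == pytest.approx(0.0, abs=1e-9)
        assert azi == pytest.approx(90.0, abs=1e-9)

    def test_too_few_points_flagged(self):
        inc, azi = leaf_angles(PointCloud(points=np.zeros((3, 3))), (0, 0))
        assert math.isnan(inc) and math.isnan(azi)

    def test_angle_recovery_on_synthetic_leaves(self):
        from maizefusion.plant_segmentation import SegmentationResult
        from maizefusion.traits_metrics import extract_traits

        cfg = FieldConfig(n_rows=2, plants_per_row=4, growth_stage=0.5,
                          point_density=3000, seed=5)
        scene = generate_field(cfg)
        from maizefusion.ground_filter import csf_ground, remove_ground

        canopy = remove_ground(scene.cloud, csf_ground(scene.cloud))
        seg = SegmentationResult(
            plant_id=canopy.labels["plant_id"].astype(np.int64),
            stem_seeds=np.array(list(scene.plant_positions.values())),
            organ_id=canopy.labels["organ_id"].astype(np.int64))
        est = extract_traits(canopy, seg)
        for trait in ("leaf_inclination", "leaf_azimuth"):
            rep = evaluate(scene.traits, est, trait)
            err = wrapped_difference(rep.pairs["value_est"], rep.pairs["value_ref"]) \
                if trait == "leaf_azimuth" else \
                rep.pairs["value_est"] - rep.pairs["value_ref"]
            assert np.abs(err).mean() <= 5.0


class TestCrownSize:
    def test_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.5]])
        area, ok = crown_size(PointCloud(points=pts))
        assert ok and area == pytest.approx(1.0)

    def test_collinear_flagged_zero(self):
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 2, 0]])
        area, ok = crown_size(PointCloud(points=pts))
        assert not ok and area == 0.0

    def test_hull_matches_bruteforce_triples(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, size=(25, 2)),
                               np.zeros(25)])
        area, ok = crown_size(PointCloud(points=pts))
        # O(n^3) oracle: max triangle-fan area over hull = max over all
        # convex polygons; compute via shoelace on the true hull ordering
        best = 0.0
        from itertools import combinations

        for tri in combinations(range(25), 3):
            a, b, c = pts[list(tri), :2]
            ab, ac = b - a, c - a
            best = max(best, abs(ab[0] * ac[1] - ab[1] * ac[0]) / 2)
        assert ok and area >= best - 1e-12
        # hull area cannot exceed the bounding box of the points
        assert area <= 1.0


class TestLeafLength:
    def test_straight_leaf_within_five_percent(self, rng):
        true_len = 0.5
        t = rng.uniform(0, 1, 400)
        direction = np.array([math.cos(0.6), 0.0, math.sin(0.6)])
        pts = np.array([0.02, 0, 0.3]) + t[:, None] * true_len * direction
        pts += rng.normal(0, 0.002, pts.shape)
        est = leaf_length(PointCloud(points=pts), (0.0, 0.0))
        assert abs(est - true_len) <= 0.05 * true_len

    def test_single_bin_zero(self):
        pts = np.tile([[0.1, 0.0, 0.5]], (10, 1))
        assert leaf_length(PointCloud(points=pts), (0, 0)) == 0.0

    def test_arc_at_least_chord(self, rng):
        # drooping parabolic midrib: polyline length >= straight chord
        t = np.sort(rng.uniform(0, 1, 300))
        chord = np.array([0.4, 0.0, 0.3])
        sag = 4 * t * (1 - t) * 0.06
        pts = np.array([0.01, 0, 0.2]) + t[:, None] * chord
        pts[:, 2] -= sag
        est = leaf_length(PointCloud(points=pts), (0.0, 0.0))
        assert est >= np.linalg.norm(chord) - 1e-6

    def test_too_few_points(self):
        assert math.isnan(leaf_length(PointCloud(points=np.zeros((3, 3))), (0, 0)))


class TestEvaluate:
    def table(self, values, trait="plant_height"):
        return TraitTable.from_records(
            [("d1", i, -1, trait, v, "m") for i, v in enumerate(values)])

    def test_perfect_prediction(self):
        rep = evaluate(self.table([1, 2, 3]), self.table([1, 2, 3]),
                       "plant_height")
        assert rep.r_squared == 1.0
        assert rep.mse == rep.rmse == rep.mae == 0.0

    def test_worked_example(self):
        rep = evaluate(self.table([1, 2, 3, 4]), self.table([2, 2, 4, 4]),
                       "plant_height")
        assert rep.m == 4
        assert rep.r_squared == pytest.approx(0.6)
        assert rep.mse == pytest.approx(0.5)
        assert rep.rmse == pytest.approx(0.70710678, abs=1e-8)
        assert rep.mae == pytest.approx(0.5)

    def test_null_model_zero_r2(self):
        v = [1.0, 2.0, 3.0, 6.0]
        rep = evaluate(self.table(v), self.table([np.mean(v)] * 4),
                       "plant_height")
        assert rep.r_squared == pytest.approx(0.0)

    def test_zero_variance_flagged(self):
        rep = evaluate(self.table([2, 2, 2]), self.table([1, 2, 3]),
                       "plant_height")
        assert rep.zero_variance and math.isnan(rep.r_squared)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            evaluate(self.table([1]), self.table([1]), "plant_height")

    def test_azimuth_wrapped(self):
        ref = self.table([359.0, 1.0, 180.0], trait="leaf_azimuth")
        est = self.table([1.0, 359.0, 182.0], trait="leaf_azimuth")
        rep = evaluate(ref, est, "leaf_azimuth")
        assert rep.mae == pytest.approx(2.0)

    def test_unmatched_keys_reported(self):
        rep = evaluate(self.table([1, 2, 3, 4]), self.table([1, 2, 3]),
                       "plant_height")
        assert rep.m == 3 and rep.unmatched_reference == 1

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20),
           st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_r2_identity_and_metric_inequalities(self, values, seed):
        v = np.asarray(values)
        rng = np.random.default_rng(seed)
        vp = v + rng.normal(0, 1.0, v.shape)
        if np.var(v) == 0:
            return
        r2, mse, rmse, mae, flag = regression_metrics(v, vp)
        assert not flag
        ss_res = np.sum((v - vp) ** 2)
        ss_tot = np.sum((v - v.mean()) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12, abs=1e-12)
        assert rmse == pytest.approx(math.sqrt(mse), abs=1e-12)
        assert mae <= rmse + 1e-12

    @given(st.floats(0, 360), st.floats(0, 360))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_wrapped_difference_range(self, a, b):
        d = float(wrapped_difference(a, b))
        assert -180.0 < d <= 180.0
        assert abs(d) <= 180.0
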