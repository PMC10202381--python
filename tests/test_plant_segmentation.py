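import numpy as np
import pytest
from scipy.spatial import cKDTree

from maizefusion import (
    FieldConfig,
    PointCloud,
    ValidationError,
    density_projection,
    generate_field,
    grow_plants,
    label_accuracy,
    quickshift_seeds,
    segment_population,
    split_stem_leaves,
)
from maizefusion.plant_segmentation import DensityGrid


def brute_force_modes(grid, window, min_density):
    """Naive oracle: cells >= min_density with no higher-ranked cell within
    Euclidean distance `window` (in cells).  Rank = (count, then smaller
    (row, col) wins ties), mirroring the documented plateau tie-break."""
    out = []
    counts = grid.counts
    H, W = counts.shape

    def outranks(r2, c2, r, c):
        if counts[r2, c2] != counts[r, c]:
            return counts[r2, c2] > counts[r, c]
        return (r2, c2) < (r, c)

    for r in range(H):
        for c in range(W):
            if counts[r, c] < min_density:
                continue
            is_mode = True
            for r2 in range(H):
                for c2 in range(W):
                    if (r2, c2) != (r, c) and outranks(r2, c2, r, c) and \
                       (r2 - r) ** 2 + (c2 - c) ** 2 <= window**2:
                        is_mode = False
                        break
                if not is_mode:
                    break
            if is_mode:
                out.append(grid.cell_center(r, c))
    return np.array(out) if out else np.empty((0, 2))


class TestDensityProjection:
    def test_four_points_one_cell(self):
        cloud = PointCloud(points=np.array([[0.001, 0.001, 0], [0.005, 0.002, 1],
                                            [0.003, 0.008, 2], [0.009, 0.009, 0]]))
        grid = density_projection(cloud, cell=0.02)
        assert grid.counts.sum() == 4
        assert grid.counts.max() == 4

    def test_uniform_grid_all_ones(self):
        # power-of-two spacing keeps cell-center offsets exact in binary fp
        base = np.arange(10) * 0.25 + 0.125
        xs, ys = np.meshgrid(base, base)
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(100)])
        grid = density_projection(PointCloud(points=pts), cell=0.25)
        assert (grid.counts == 1).all()

    def test_conservation(self, canopy_and_truth):
        canopy, _ = canopy_and_truth
        grid = density_projection(canopy)
        assert grid.counts.sum() == len(canopy)

    def test_bad_cell_rejected(self, canopy_and_truth):
        with pytest.raises(ValidationError):
            density_projection(canopy_and_truth[0], cell=0.0)


class TestQuickshiftSeeds:
    def test_two_blobs_two_seeds(self, rng):
        a = rng.normal([0.3, 0.3], 0.05, size=(400, 2))
        b = rng.normal([0.9, 0.3], 0.05, size=(400, 2))
        pts = np.vstack([a, b])
        cloud = PointCloud(points=np.column_stack([pts, np.zeros(len(pts))]))
        grid = density_projection(cloud, cell=0.02)
        seeds = quickshift_seeds(grid, min_density=3)
        assert len(seeds) == 2
        d, _ = cKDTree(seeds).query([[0.3, 0.3], [0.9, 0.3]])
        assert d.max() <= 0.06

    def test_single_blob_one_seed(self, rng):
        pts = rng.normal([0.5, 0.5], 0.05, size=(500, 2))
        cloud = PointCloud(points=np.column_stack([pts, np.zeros(500)]))
        seeds = quickshift_seeds(density_projection(cloud, cell=0.02),
                                 min_density=3)
        assert len(seeds) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_modes(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2.0, size=(30, 30))
        counts[rng.integers(0, 30, 5), rng.integers(0, 30, 5)] += 30
        grid = DensityGrid(cell=0.02, counts=counts, origin=(0.0, 0.0))
        got = quickshift_seeds(grid, window=5, min_density=10)
        expected = brute_force_modes(grid, window=5, min_density=10)
        assert len(got) == len(expected)
        if len(got):
            d, _ = cKDTree(expected).query(got)
            assert d.max() == 0.0

    def test_empty_after_filter(self):
        grid = DensityGrid(cell=0.02, counts=np.ones((5, 5), int), origin=(0, 0))
        assert len(quickshift_seeds(grid, min_density=100)) == 0

    def test_field_seed_count_and_placement(self, separated_field):
        from maizefusion.ground_filter import csf_ground, remove_ground

        canopy = remove_ground(separated_field.cloud,
                               csf_ground(separated_field.cloud))
        seeds = quickshift_seeds(density_projection(canopy))
        truth = np.array(list(separated_field.plant_positions.values()))
        d, _ = cKDTree(seeds).query(truth)
        assert d.max() <= 0.05          # every plant has a nearby seed
        assert len(seeds) >= len(truth)  # spurious extras allowed, misses not


class TestGrowPlants:
    def test_single_plant_single_label(self):
        cfg = FieldConfig(n_rows=1, plants_per_row=1, growth_stage=0.5,
                          point_density=4000, seed=3, occlusion=0.0)
        scene = generate_field(cfg)
        from maizefusion.ground_filter import csf_ground, remove_ground

        canopy = remove_ground(scene.cloud, csf_ground(scene.cloud))
        plant_mask = canopy.labels["plant_id"] == 0
        plant = canopy.select(plant_mask)
        seg = grow_plants(plant, np.array([scene.plant_positions[0]]))
        assert (seg.plant_id == 0).all()

    def test_separated_plants_partition_matches_truth(self, separated_field):
        from maizefusion.ground_filter import csf_ground, remove_ground

        canopy = remove_ground(separated_field.cloud,
                               csf_ground(separated_field.cloud))
        seg = segment_population(canopy)
        acc = label_accuracy(canopy.labels["plant_id"], seg.plant_id)
        assert acc >= 0.95

    def test_no_seeds_rejected(self, canopy_and_truth):
        with pytest.raises(ValidationError):
            grow_plants(canopy_and_truth[0], np.empty((0, 2)))

    def test_determinism(self, canopy_and_truth):
        canopy, scene = canopy_and_truth
        seeds = np.array(list(scene.plant_positions.values()))
        a = grow_plants(canopy, seeds)
        b = grow_plants(canopy, seeds)
        np.testing.assert_array_equal(a.plant_id, b.plant_id)

    def test_every_label_has_a_seed(self, canopy_and_truth):
        canopy, scene = canopy_and_truth
        seeds = np.array(list(scene.plant_positions.values()))
        seg = grow_plants(canopy, seeds)
        assert seg.plant_id.max() < len(seeds)
        assert seg.plant_id.min() >= -1

    def test_guided_transform_applied(self, canopy_and_truth):
        canopy, scene = canopy_and_truth
        seeds = np.array(list(scene.plant_positions.values()))
        shift = np.eye(4)
        shift[:2, 3] = [0.5, -0.2]
        seg = grow_plants(canopy, np.empty((0, 2)),
                          guided_seeds=seeds - [0.5, -0.2],
                          guided_transform=shift)
        assert seg.provenance == "guided"
        ref = grow_plants(canopy, seeds)
        np.testing.assert_array_equal(seg.plant_id, ref.plant_id)


class TestSplitStemLeaves:
    def test_six_leaf_plant_exact_split(self):
        cfg = FieldConfig(n_rows=1, plants_per_row=1, growth_stage=0.5,
                          point_density=3000, seed=2)
        scene = generate_field(cfg)
        from maizefusion.ground_filter import csf_ground, remove_ground

        canopy = remove_ground(scene.cloud, csf_ground(scene.cloud))
        plant = canopy.select(canopy.labels["plant_id"] == 0)
        organ, ok = split_stem_leaves(plant)
        assert ok
        assert organ.max() == 6          # six leaves at this stage
        assert (organ == 0).sum() > 0    # and one stem

    def test_stem_only_plant_all_stem(self, rng):
        ang = rng.uniform(0, 2 * np.pi, 300)
        pts = np.column_stack([0.012 * np.cos(ang), 0.012 * np.sin(ang),
                               rng.uniform(0, 1.2, 300)])
        organ, ok = split_stem_leaves(PointCloud(points=pts))
        assert ok
        assert (organ == 0).all()

    def test_too_small_plant_flagged(self, rng):
        organ, ok = split_stem_leaves(PointCloud(points=rng.normal(size=(10, 3))))
        assert not ok
        assert (organ == -1).all()

    def test_organ_accuracy_twelve_plant_scene(self):
        from maizefusion.ground_filter import csf_ground, remove_ground

        num = den = 0.0
        cfg = FieldConfig(n_rows=3, plants_per_row=4, growth_stage=0.45,
                          point_density=3000, seed=1)
        scene = generate_field(cfg)
        canopy = remove_ground(scene.cloud, csf_ground(scene.cloud))
        for pid in range(12):
            idx = np.flatnonzero(canopy.labels["plant_id"] == pid)
            plant = canopy.select(idx)
            organ, _ = split_stem_leaves(plant)
            num += label_accuracy(plant.labels["organ_id"], organ) * len(idx)
            den += len(idx)
        assert num / den >= 0.85


class TestLabelAccuracy:
    def test_perfect(self):
        t = np.array([0, 0, 1, 1])
        assert label_accuracy(t, t) == 1.0

    def test_split_penalized(self):
        truth = np.array([0, 0, 0, 0])
        pred = np.array([0, 0, 1, 1])
        assert label_accuracy(truth, pred) == 0.5

    def test_merge_penalized(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 0, 0, 0])
        assert label_accuracy(truth, pred) == 0.5

    def test_unassigned_not_correct(self):
        truth = np.array([0, 0])
        pred = np.array([-1, 0])
        assert label_accuracy(truth, pred) == 0.5
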