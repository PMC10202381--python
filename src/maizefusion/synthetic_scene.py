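"""Seeded synthetic maize fields for end-to-end pipeline testing.

Generates labeled point clouds, orthorectified top-view images, known
cloud-to-image misalignments and ground-truth trait tables for a parametric
maize canopy: vertical stems on a 0.60 m x 0.30 m planting grid, leaves as
drooping parabolic-arc midribs with lateral width, rough ground with
drip-tape ridges, and white square calibration markers at the field corners.

Ground-truth traits are computed from the generative parameters, never from
the sampled points, so estimator error is attributable to the pipeline.
Identical (config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .io_formats import OrthoImage, PointCloud, TraitTable

# canopy scale constants (meters / degrees); per-plant jitter is applied on top
H_MAX = 2.4            # asymptotic stem height of the logistic growth curve
LOGISTIC_K = 8.0       # growth-curve steepness in growth-stage units
LOGISTIC_MID = 0.55    # growth stage of the inflection point
STEM_RADIUS = 0.012
MAX_LEAVES = 10
LEAF_WIDTH = 0.06
MARKER_SIZE = 0.12     # side of the white calibration squares

PLANT_COLOR = (44, 160, 44)
SOIL_COLOR = (120, 92, 60)
MARKER_COLOR = (255, 255, 255)


def logistic_height(growth_stage: float) -> float:
    """Nominal stem height (m) at a growth stage in [0, 1]."""
    return H_MAX / (1.0 + math.exp(-LOGISTIC_K * (growth_stage - LOGISTIC_MID)))


# ---------------------------------------------------------------------------
# transforms (4x4 homogeneous, z-rotation + uniform scale + translation)
# ---------------------------------------------------------------------------


def make_rigid_scale(rotation_z: float, scale: float, translation) -> np.ndarray:
    """4x4 matrix p' = scale * Rz(rotation_z) @ p + translation."""
    if not (scale > 0):
        raise ValidationError("scale must be > 0")
    c, s = math.cos(rotation_z), math.sin(rotation_z)
    T = np.eye(4)
    T[:3, :3] = scale * np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    T[:3, 3] = np.asarray(translation, dtype=float)
    return T


def apply_transform(points: np.ndarray, T: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    return pts @ T[:3, :3].T + T[:3, 3]


def transform_params(T: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(rotation_z, scale, translation) of a rigid+scale 4x4 matrix."""
    scale = float(np.linalg.norm(T[:2, 0]))
    rot = float(math.atan2(T[1, 0], T[0, 0]))
    return rot, scale, T[:3, 3].copy()


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldConfig:
    """Planting layout and acquisition parameters of a synthetic field.

    Spacings follow the experimental layout (rows 0.60 m apart, plants
    0.30 m apart within rows).  ``growth_stage`` in [0, 1] spans the V3..R6
    morphology range through a logistic height curve.
    """

    n_rows: int = 2
    plants_per_row: int = 5
    row_spacing: float = 0.60
    plant_spacing: float = 0.30
    growth_stage: float = 0.5
    ground_roughness: float = 0.02
    tape_amplitude: float = 0.03
    point_density: float = 5e4
    seed: int = 0
    margin: float = 0.5          # bare soil border around the planting grid
    gsd: float = 0.005           # rendered image ground sampling distance
    occlusion: float = 0.03      # top-down shadowing rate per covering point
    low_drop_fraction: float = 0.0   # fraction of low (z < 0.3 m) points removed

    def __post_init__(self):
        if self.n_rows < 1 or self.plants_per_row < 1:
            raise ValidationError("field must contain at least one plant")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValidationError("spacings must be > 0")
        if not (0.0 <= self.growth_stage <= 1.0):
            raise ValidationError("growth_stage must lie in [0, 1]")
        if self.point_density <= 0:
            raise ValidationError("point_density must be > 0")
        if self.ground_roughness < 0 or self.tape_amplitude < 0:
            raise ValidationError("roughness/tape amplitude must be >= 0")


@dataclass
class SceneTruth:
    """One acquisition date: cloud + image + generative ground truth."""

    cloud: PointCloud
    image: OrthoImage
    traits: TraitTable
    cloud_to_image_offset: np.ndarray  # 4x4 applied to the world-frame cloud
    calibration_markers: list[tuple[float, float]]
    plant_positions: dict[int, tuple[float, float]]
    config: FieldConfig
    date_tag: str = "d1"


# ---------------------------------------------------------------------------
# generative geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _LeafParams:
    insertion_frac: float
    inclination_deg: float
    azimuth_deg: float
    rel_chord: float
    droop_frac: float


@dataclass(frozen=True)
class _PlantParams:
    plant_id: int
    x: float
    y: float
    height_scale: float
    leaves: tuple[_LeafParams, ...]


def _plant_params(plant_id: int, x: float, y: float, rng: np.random.Generator) -> _PlantParams:
    height_scale = float(rng.uniform(0.85, 1.15))
    plane = float(rng.uniform(0.0, 360.0))  # distichous leaf plane azimuth
    leaves = []
    pair_chord = 0.0
    for l in range(MAX_LEAVES):
        side = 0.0 if l % 2 == 0 else 180.0
        if l % 2 == 0:
            # opposite leaves of a pair share a base length (balanced canopy)
            pair_chord = float(rng.uniform(0.3, 0.48))
        leaves.append(
            _LeafParams(
                insertion_frac=0.15 + 0.72 * (l + 1) / (MAX_LEAVES + 1),
                # upper leaves insert more erect (regular maize phyllotaxy);
                # rank-structured angles keep midribs from crossing
                inclination_deg=float(28.0 + 30.0 * (l + 1) / MAX_LEAVES
                                      + rng.uniform(-7.0, 7.0)),
                azimuth_deg=float((plane + side + rng.uniform(-25.0, 25.0)) % 360.0),
                rel_chord=pair_chord * float(rng.uniform(0.93, 1.07)),
                droop_frac=float(rng.uniform(0.04, 0.1)),
            )
        )
    return _PlantParams(plant_id, x, y, height_scale, tuple(leaves))


def _n_leaves(growth_stage: float) -> int:
    return int(np.clip(2 + round(8 * growth_stage), 2, MAX_LEAVES))


def _leaf_geometry(plant: _PlantParams, leaf: _LeafParams, growth_stage: float):
    """Midrib curve q(t), chord direction, and generative truths for one leaf.

    The midrib is a planar parabolic arc below its chord; the chord starts on
    the stem surface at the insertion height and defines the true inclination
    (angle to horizontal) and azimuth (bearing of its xy projection).
    """
    height = plant.height_scale * logistic_height(growth_stage)
    h_ins = leaf.insertion_frac * height
    theta = math.radians(leaf.inclination_deg)
    phi = math.radians(leaf.azimuth_deg)
    # cap the chord so the arc never tops the stem (stem apex defines height)
    chord = min(
        leaf.rel_chord * max(height, 0.25),
        max(0.93 * height - h_ins, 0.02) / max(math.sin(theta), 0.2),
    )
    d = np.array([math.cos(phi) * math.cos(theta),
                  math.sin(phi) * math.cos(theta),
                  math.sin(theta)])
    # in-plane downward normal (perpendicular to the chord, negative z part)
    n_hat = np.array([math.cos(phi) * math.sin(theta),
                      math.sin(phi) * math.sin(theta),
                      -math.cos(theta)])
    p0 = np.array([plant.x + STEM_RADIUS * math.cos(phi),
                   plant.y + STEM_RADIUS * math.sin(phi),
                   h_ins])
    droop = leaf.droop_frac * chord

    def q(t):
        t = np.asarray(t, dtype=float)[..., None]
        return p0 + t * chord * d + 4.0 * t * (1.0 - t) * droop * n_hat

    # arc length from the parametric form (truth, independent of sampling)
    ts = np.linspace(0.0, 1.0, 257)
    seg = np.diff(q(ts), axis=0)
    arc_length = float(np.linalg.norm(seg, axis=1).sum())
    tip = q(1.0)
    return q, arc_length, tip, h_ins, chord


def _lateral(phi_deg: float) -> np.ndarray:
    phi = math.radians(phi_deg)
    return np.array([-math.sin(phi), math.cos(phi), 0.0])


class _GroundModel:
    """Smooth random terrain: plane + sinusoid mixture + drip-tape ridges."""

    def __init__(self, config: FieldConfig, rng: np.random.Generator, row_ys):
        self.roughness = config.ground_roughness
        self.tape_amplitude = config.tape_amplitude
        self.row_ys = np.asarray(row_ys)
        k = 6
        self.freqs = rng.uniform(0.3, 1.6, size=(k, 2))   # cycles per meter
        self.phases = rng.uniform(0.0, 2 * np.pi, size=k)
        amps = rng.uniform(0.5, 1.0, size=k)
        # normalize so the sinusoid mixture has unit std, then scale
        self.amps = amps / math.sqrt(0.5 * float(np.sum(amps**2)))

    def height(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        for a, (fx, fy), ph in zip(self.amps, self.freqs, self.phases):
            z = z + a * np.cos(2 * np.pi * (fx * x + fy * y) + ph)
        z = z * self.roughness
        if self.tape_amplitude > 0 and len(self.row_ys):
            # drip tape runs alongside each row, 0.15 m to its +y side
            dy = np.abs(y[..., None] - (self.row_ys + 0.15))
            ridge = np.exp(-((dy / 0.045) ** 2)).max(axis=-1)
            z = z + self.tape_amplitude * ridge
        return z


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _sample_plant(plant: _PlantParams, ground: _GroundModel, growth_stage: float,
                  density: float, rng: np.random.Generator):
    """Points, organ labels and truth records for one plant."""
    height = plant.height_scale * logistic_height(growth_stage)
    base_z = float(ground.height(plant.x, plant.y))
    pts, organs = [], []

    stem_area = 2 * np.pi * STEM_RADIUS * height
    n_stem = max(int(rng.poisson(density * stem_area)), 40)
    ang = rng.uniform(0, 2 * np.pi, n_stem)
    z = rng.uniform(0, height, n_stem)
    pts.append(np.column_stack([
        plant.x + STEM_RADIUS * np.cos(ang),
        plant.y + STEM_RADIUS * np.sin(ang),
        base_z + z,
    ]))
    organs.append(np.zeros(n_stem, dtype=np.int32))

    # apex whorl: the furled emerging leaves form a dense cluster at the
    # stem tip, so the canopy's top is densely sampled like real maize
    n_apex = max(int(rng.poisson(density * 0.0015)), 30)
    apex_dz = np.abs(rng.normal(0.0, 0.012, n_apex))
    apex_r = rng.uniform(0, 0.02, n_apex)
    apex_a = rng.uniform(0, 2 * np.pi, n_apex)
    pts.append(np.column_stack([
        plant.x + apex_r * np.cos(apex_a),
        plant.y + apex_r * np.sin(apex_a),
        base_z + np.clip(height - apex_dz, 0.8 * height, height),
    ]))
    organs.append(np.zeros(n_apex, dtype=np.int32))

    n_leaves = _n_leaves(growth_stage)
    records = []
    tips = []
    for l in range(n_leaves):
        leaf = plant.leaves[l]
        q, arc, tip, h_ins, chord = _leaf_geometry(plant, leaf, growth_stage)
        tips.append(tip[:2])
        area = arc * (0.55 * LEAF_WIDTH + 0.005)
        n_leaf = max(int(rng.poisson(density * area)), 25)
        t = rng.uniform(0, 1, n_leaf)
        width = LEAF_WIDTH * 4 * t * (1 - t) + 0.005
        u = rng.uniform(-0.5, 0.5, n_leaf) * width
        noise = rng.normal(0.0, 0.002, size=(n_leaf, 3))
        leaf_pts = q(t) + u[:, None] * _lateral(leaf.azimuth_deg)[None, :] + noise
        leaf_pts[:, 2] += base_z
        pts.append(leaf_pts)
        organs.append(np.full(n_leaf, l + 1, dtype=np.int32))
        records += [
            ("", plant.plant_id, l + 1, "leaf_inclination", leaf.inclination_deg, "deg"),
            ("", plant.plant_id, l + 1, "leaf_azimuth", leaf.azimuth_deg, "deg"),
            ("", plant.plant_id, l + 1, "leaf_length", arc, "m"),
        ]

    records.append(("", plant.plant_id, -1, "plant_height", height, "m"))
    records.append(("", plant.plant_id, -1, "crown_size", _hull_area(tips), "m2"))
    return np.vstack(pts), np.concatenate(organs), records


def _hull_area(xy_points) -> float:
    xy = np.asarray(xy_points, dtype=float)
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # 2D hull: volume is the area
    except QhullError:
        return 0.0


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_field(config: FieldConfig, date_tag: str = "d1",
                   offset: np.ndarray | None = None) -> SceneTruth:
    """Generate one acquisition: labeled cloud, rendered image, truth traits.

    The image is rendered in the world frame; the returned cloud has
    ``offset`` (default identity) applied, and that matrix is stored as
    ``cloud_to_image_offset`` — the misalignment registration must undo.
    """
    ss = np.random.SeedSequence(config.seed)
    n_plants = config.n_rows * config.plants_per_row
    keys = ss.spawn(n_plants + 3)
    rng_layout = np.random.default_rng(keys[n_plants])
    rng_ground = np.random.default_rng(keys[n_plants + 1])
    rng_scene = np.random.default_rng(keys[n_plants + 2])

    row_ys = np.arange(config.n_rows) * config.row_spacing
    col_xs = np.arange(config.plants_per_row) * config.plant_spacing
    x_min, x_max = col_xs[0] - config.margin, col_xs[-1] + config.margin
    y_min, y_max = row_ys[0] - config.margin, row_ys[-1] + config.margin

    ground = _GroundModel(config, rng_ground, row_ys)

    plants = []
    pid = 0
    for r in range(config.n_rows):
        for c in range(config.plants_per_row):
            jit = rng_layout.uniform(-0.01, 0.01, 2)
            plants.append(
                _plant_params(pid, float(col_xs[c] + jit[0]), float(row_ys[r] + jit[1]),
                              np.random.default_rng(keys[pid]))
            )
            pid += 1

    all_pts, all_plant_id, all_organ, all_ground = [], [], [], []
    records = []
    for plant in plants:
        # per-plant sampling stream keyed by (seed, plant_id, stage-invariant)
        rng_p = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1000 + plant.plant_id,))
        )
        pts, organs, recs = _sample_plant(plant, ground, config.growth_stage,
                                          config.point_density, rng_p)
        all_pts.append(pts)
        all_plant_id.append(np.full(len(pts), plant.plant_id, dtype=np.int32))
        all_organ.append(organs)
        all_ground.append(np.zeros(len(pts), dtype=np.int32))
        records += [(date_tag, *r[1:]) for r in recs]

    # bare ground
    area = (x_max - x_min) * (y_max - y_min)
    n_gnd = max(int(rng_scene.poisson(config.point_density * area)), 200)
    gx = rng_scene.uniform(x_min, x_max, n_gnd)
    gy = rng_scene.uniform(y_min, y_max, n_gnd)
    gz = ground.height(gx, gy)
    all_pts.append(np.column_stack([gx, gy, gz]))
    all_plant_id.append(np.full(n_gnd, -1, dtype=np.int32))
    all_organ.append(np.full(n_gnd, -1, dtype=np.int32))
    all_ground.append(np.ones(n_gnd, dtype=np.int32))

    # calibration markers: raised white squares at the four field corners
    markers = [(x_min + 0.1, y_min + 0.1), (x_max - 0.1, y_min + 0.1),
               (x_min + 0.1, y_max - 0.1), (x_max - 0.1, y_max - 0.1)]
    # calibration boards are solid reflective targets: dense returns
    n_mk = max(int(config.point_density * MARKER_SIZE**2), 600)
    for mx, my in markers:
        ox = rng_scene.uniform(-MARKER_SIZE / 2, MARKER_SIZE / 2, n_mk)
        oy = rng_scene.uniform(-MARKER_SIZE / 2, MARKER_SIZE / 2, n_mk)
        # rigid flat board: one elevation for the whole square
        mz = np.full(n_mk, float(ground.height(mx, my)) + 0.02)
        mz += rng_scene.normal(0.0, 0.002, n_mk)
        all_pts.append(np.column_stack([mx + ox, my + oy, mz]))
        all_plant_id.append(np.full(n_mk, -1, dtype=np.int32))
        all_organ.append(np.full(n_mk, -1, dtype=np.int32))
        all_ground.append(np.ones(n_mk, dtype=np.int32))

    points = np.vstack(all_pts)
    plant_id = np.concatenate(all_plant_id)
    organ_id = np.concatenate(all_organ)
    ground_lab = np.concatenate(all_ground)

    n_marker = 4 * n_mk
    colors = np.empty((len(points), 3), dtype=np.uint8)
    colors[ground_lab == 0] = PLANT_COLOR
    colors[ground_lab == 1] = SOIL_COLOR
    colors[len(points) - n_marker:] = MARKER_COLOR

    # top-down occlusion: points shadowed by many covering points are lost
    keep = _occlude(points, config.occlusion, rng_scene)
    if config.low_drop_fraction > 0:
        low = points[:, 2] < 0.3
        drop = rng_scene.uniform(size=len(points)) < config.low_drop_fraction
        keep &= ~(low & drop & (ground_lab == 0))
    points, colors = points[keep], colors[keep]
    plant_id, organ_id, ground_lab = plant_id[keep], organ_id[keep], ground_lab[keep]

    image = _render_image(config, plants, ground, markers,
                          (x_min, x_max, y_min, y_max), date_tag, rng_scene)

    if offset is None:
        offset = np.eye(4)
    cloud = PointCloud(
        points=apply_transform(points, offset),
        colors=colors,
        labels={"ground": ground_lab, "plant_id": plant_id, "organ_id": organ_id},
        frame_id="cloud" if not np.allclose(offset, np.eye(4)) else "world",
        date_tag=date_tag,
    )
    traits = TraitTable.from_records(records)
    return SceneTruth(
        cloud=cloud, image=image, traits=traits,
        cloud_to_image_offset=np.asarray(offset, dtype=float),
        calibration_markers=markers,
        plant_positions={p.plant_id: (p.x, p.y) for p in plants},
        config=config, date_tag=date_tag,
    )


def _occlude(points: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Delete points shadowed from above; loss rises with cover count."""
    if rate <= 0 or len(points) == 0:
        return np.ones(len(points), dtype=bool)
    cell = 0.02
    ij = np.floor(points[:, :2] / cell).astype(np.int64)
    key = ij[:, 0] * 1_000_003 + ij[:, 1]
    order = np.lexsort((-points[:, 2], key))
    sk = key[order]
    starts = np.flatnonzero(np.r_[True, sk[1:] != sk[:-1]])
    rank = np.arange(len(sk)) - np.repeat(starts, np.diff(np.r_[starts, len(sk)]))
    p_keep = np.exp(-rate * rank)
    keep_sorted = rng.uniform(size=len(sk)) < p_keep
    keep = np.empty(len(points), dtype=bool)
    keep[order] = keep_sorted
    return keep


def _render_image(config, plants, ground, markers, extent, date_tag, rng):
    """Orthographic render: green canopy on brown soil with white markers."""
    x_min, x_max, y_min, y_max = extent
    gsd = config.gsd
    W = int(math.ceil((x_max - x_min) / gsd)) + 1
    H = int(math.ceil((y_max - y_min) / gsd)) + 1
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = SOIL_COLOR
    origin = (x_min, y_max)

    mask = np.zeros((H, W), dtype=bool)
    for plant in plants:
        pts, _, _ = _sample_plant(
            plant, ground, config.growth_stage,
            # render density decoupled from cloud density so silhouettes close
            max(config.point_density, 2.0e4),
            np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed,
                                       spawn_key=(5000 + plant.plant_id,))
            ),
        )
        c = np.round((pts[:, 0] - origin[0]) / gsd).astype(int)
        r = np.round((origin[1] - pts[:, 1]) / gsd).astype(int)
        ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        # 1-pixel splat cross to close silhouette holes
        for dr, dc in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, cc = r[ok] + dr, c[ok] + dc
            good = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            mask[rr[good], cc[good]] = True
    img[mask] = PLANT_COLOR

    half = MARKER_SIZE / 2
    for mx, my in markers:
        c0 = int(round((mx - half - origin[0]) / gsd))
        c1 = int(round((mx + half - origin[0]) / gsd))
        r0 = int(round((origin[1] - (my + half)) / gsd))
        r1 = int(round((origin[1] - (my - half)) / gsd))
        img[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1] = MARKER_COLOR

    return OrthoImage(pixels=img, gsd=gsd, origin=origin, date_tag=date_tag)


def make_time_series(config: FieldConfig, n_dates: int,
                     offsets: list[np.ndarray] | None = None,
                     stage_step: float = 0.12) -> list[SceneTruth]:
    """Generate a growth series with per-date cloud-frame misalignments.

    Growth stage rises monotonically; plant positions and morphology are
    fixed; each date's cloud is perturbed by its own rigid+scale offset
    (rotation <= 5 deg, translation <= 0.3 m, scale in [0.98, 1.02]) recorded
    in the scene truth.  Later dates lose a rising fraction of low points,
    mimicking occlusion by leaf crossing and overlap.
    """
    if n_dates < 1:
        raise ValidationError("n_dates must be >= 1")
    if offsets is not None and len(offsets) != n_dates:
        raise ValidationError("offsets must have one entry per date")

    g0 = config.growth_stage
    stages = np.linspace(g0, min(1.0, g0 + stage_step * (n_dates - 1)), n_dates)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(77,)))
    scenes = []
    for d in range(n_dates):
        if offsets is not None:
            T = np.asarray(offsets[d], dtype=float)
        elif d == 0:
            T = np.eye(4)  # date 1 is the reference frame
        else:
            ang = math.radians(rng.uniform(-5.0, 5.0))
            scale = rng.uniform(0.98, 1.02)
            direction = rng.uniform(0, 2 * np.pi)
            mag = rng.uniform(0.05, 0.28)
            t = np.array([mag * math.cos(direction), mag * math.sin(direction),
                          rng.uniform(-0.05, 0.05)])
            T = make_rigid_scale(ang, scale, t)
        drop = 0.0 if n_dates == 1 else 0.4 * d / (n_dates - 1)
        cfg_d = replace(config, growth_stage=float(stages[d]),
                        low_drop_fraction=drop)
        scenes.append(generate_field(cfg_d, date_tag=f"d{d + 1}", offset=T))
    return scenes


def truth_summary(scene: SceneTruth) -> TraitTable:
    """Ground-truth traits in the pipeline's output schema."""
    return scene.traits
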