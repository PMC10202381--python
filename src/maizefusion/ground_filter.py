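"""Statistical denoising and cloth-simulation ground filtering.

Noise points are removed with a KD-tree neighborhood test: a point whose
mean distance to its k nearest neighbors exceeds the global mean by more
than ``sigma_mult`` standard deviations is discarded.

Ground classification follows the cloth simulation filter: the cloud is
inverted (z -> -z) so the terrain becomes its upper surface, a regular grid
of cloth particles is dropped from above under gravity (the external force
of the particle dynamics m d2A/dt2 = F_ext + F_int), particles are clamped
where they penetrate the inverted surface, and the internal force is
realized as ``rigidness`` rounds of neighbor-spring relaxation per step.
Points within ``class_threshold`` of the settled, re-inverted cloth are
ground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io_formats import PointCloud

# integration constants mirroring the reference cloth implementation
DT = 0.65
DAMPING = 0.01
GRAVITY = 0.2  # internal units; displacement per step ~ GRAVITY * DT^2


@dataclass
class ClothState:
    """Cloth particle grid draped over the inverted cloud."""

    heights: np.ndarray          # (rows, cols) particle z in the inverted frame
    prev_heights: np.ndarray
    movable: np.ndarray          # False once clamped on the surface
    collision: np.ndarray        # per-cell inverted surface height
    x0: float
    y0: float
    grid_res: float

    @property
    def shape(self):
        return self.heights.shape


@dataclass
class GroundClassification:
    ground_idx: np.ndarray
    nonground_idx: np.ndarray
    distance_threshold: float
    iterations_used: int

    def __post_init__(self):
        n = len(self.ground_idx) + len(self.nonground_idx)
        union = np.union1d(self.ground_idx, self.nonground_idx)
        if len(union) != n:
            raise ValidationError("ground/nonground sets must be disjoint")


def denoise_statistical(cloud: PointCloud, k_neighbors: int = 8,
                        sigma_mult: float = 2.0) -> tuple[PointCloud, np.ndarray]:
    """Remove points with anomalously large mean k-NN distance."""
    n = len(cloud)
    if n <= k_neighbors:
        raise ValidationError(
            f"need more than k_neighbors={k_neighbors} points, got {n}"
        )
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + sigma_mult * mean_d.std()
    removed = np.flatnonzero(mean_d > cutoff)
    keep = mean_d <= cutoff
    return cloud.select(keep), removed


def _init_cloth(points: np.ndarray, grid_res: float) -> ClothState:
    """Grid covering the xy bounding box, collision surface per cell.

    The collision height of a cell is the inverted-frame height of that
    cell's lowest original point (the first surface a falling cloth meets);
    empty cells borrow it from the nearest occupied cell.
    """
    inv_z = -points[:, 2]
    x0, y0 = points[:, 0].min(), points[:, 1].min()
    nx = int(np.ceil((points[:, 0].max() - x0) / grid_res)) + 1
    ny = int(np.ceil((points[:, 1].max() - y0) / grid_res)) + 1
    if nx < 2 or ny < 2:
        raise ValidationError(
            f"cloth grid is {ny} x {nx} particles; need at least 2 x 2 "
            "(cloud xy extent smaller than one grid cell)"
        )

    ci = np.clip(np.round((points[:, 0] - x0) / grid_res).astype(int), 0, nx - 1)
    cj = np.clip(np.round((points[:, 1] - y0) / grid_res).astype(int), 0, ny - 1)
    collision = np.full((ny, nx), -np.inf)
    np.maximum.at(collision, (cj, ci), inv_z)

    empty = ~np.isfinite(collision)
    if empty.any():
        jj, ii = np.nonzero(~empty)
        tree = cKDTree(np.column_stack([ii, jj]))
        ej, ei = np.nonzero(empty)
        _, nearest = tree.query(np.column_stack([ei, ej]))
        collision[ej, ei] = collision[jj[nearest], ii[nearest]]

    start = inv_z.max() + 0.5
    heights = np.full((ny, nx), start)
    return ClothState(
        heights=heights, prev_heights=heights.copy(),
        movable=np.ones((ny, nx), dtype=bool), collision=collision,
        x0=float(x0), y0=float(y0), grid_res=float(grid_res),
    )


def _relax(heights: np.ndarray, movable: np.ndarray, rounds: int) -> np.ndarray:
    """Internal springs: move each movable particle halfway to the mean of
    its 4-connected neighbors (edge particles use the available ones)."""
    h = heights
    for _ in range(rounds):
        padded = np.pad(h, 1, mode="edge")
        nb_sum = (padded[:-2, 1:-1] + padded[2:, 1:-1]
                  + padded[1:-1, :-2] + padded[1:-1, 2:])
        nb_cnt = np.full_like(h, 4.0)
        avg = nb_sum / nb_cnt
        h = np.where(movable, h + 0.5 * (avg - h), h)
    return h


def simulate_cloth(state: ClothState, rigidness: int = 2, max_iter: int = 500,
                   min_displacement: float = 1e-4) -> tuple[ClothState, int]:
    """Drop the cloth until it settles or the iteration budget runs out."""
    if rigidness < 1:
        raise ValidationError("rigidness must be >= 1")
    h = state.heights
    prev = state.prev_heights
    movable = state.movable
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # damped Verlet step under gravity (external force)
        new = h + (1.0 - DAMPING) * (h - prev) - GRAVITY * DT * DT
        new = np.where(movable, new, h)
        prev, h = h, new
        # collision: clamp onto the inverted surface and freeze
        hit = movable & (h <= state.collision)
        h = np.where(hit, state.collision, h)
        movable = movable & ~hit
        # internal force: spring relaxation, then re-clamp
        h = _relax(h, movable, rigidness)
        hit = movable & (h <= state.collision)
        h = np.where(hit, state.collision, h)
        movable = movable & ~hit
        disp = float(np.abs(h - prev).max())
        if disp < min_displacement:
            break
    state.heights = h
    state.prev_heights = prev
    state.movable = movable
    return state, iterations


def _cloth_height_at(state: ClothState, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the cloth surface at xy (inverted frame)."""
    gx = (xy[:, 0] - state.x0) / state.grid_res
    gy = (xy[:, 1] - state.y0) / state.grid_res
    ny, nx = state.shape
    i0 = np.clip(np.floor(gx).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(gy).astype(int), 0, ny - 2)
    fx = np.clip(gx - i0, 0.0, 1.0)
    fy = np.clip(gy - j0, 0.0, 1.0)
    h = state.heights
    return ((1 - fy) * ((1 - fx) * h[j0, i0] + fx * h[j0, i0 + 1])
            + fy * ((1 - fx) * h[j0 + 1, i0] + fx * h[j0 + 1, i0 + 1]))


def csf_ground(cloud: PointCloud, grid_res: float = 0.1, rigidness: int = 2,
               class_threshold: float = 0.05, max_iter: int = 500,
               min_displacement: float = 1e-4) -> GroundClassification:
    """Classify ground points with the cloth simulation filter."""
    if len(cloud) < 1:
        raise ValidationError("cannot filter an empty cloud")
    if not (grid_res > 0):
        raise ValidationError("grid_res must be > 0")
    state = _init_cloth(cloud.points, grid_res)
    state, iterations = simulate_cloth(state, rigidness=rigidness,
                                       max_iter=max_iter,
                                       min_displacement=min_displacement)
    cloth_inv = _cloth_height_at(state, cloud.points[:, :2])
    dist = np.abs(-cloud.points[:, 2] - cloth_inv)  # vertical gap to cloth
    is_ground = dist <= class_threshold
    return GroundClassification(
        ground_idx=np.flatnonzero(is_ground),
        nonground_idx=np.flatnonzero(~is_ground),
        distance_threshold=float(class_threshold),
        iterations_used=int(iterations),
    )


def remove_ground(cloud: PointCloud, classification: GroundClassification
                  ) -> PointCloud:
    """Non-ground subset with labels preserved."""
    total = len(classification.ground_idx) + len(classification.nonground_idx)
    if total != len(cloud):
        raise ValidationError(
            f"classification covers {total} points, cloud has {len(cloud)}"
        )
    return cloud.select(classification.nonground_idx)


def extract_ground(cloud: PointCloud, classification: GroundClassification
                   ) -> PointCloud:
    """Ground subset (for inspection or DEM-style exports)."""
    total = len(classification.ground_idx) + len(classification.nonground_idx)
    if total != len(cloud):
        raise ValidationError("classification does not match cloud size")
    return cloud.select(classification.ground_idx)
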