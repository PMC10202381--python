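"""Individual-plant and organ segmentation of ground-free canopy clouds.

Stem positions are found by mode seeking on the 2D point-density grid
(quickshift: every cell links to its nearest higher-density cell; link-tree
roots are density modes, i.e. stem seeds), plants are grown from the seed
columns over a 3D proximity graph with a global minimum-gap priority
frontier, and each plant is split into a stem column plus leaves clustered
along the stem.

"Guided" mode replaces the fresh seeds with stem positions carried over
from an earlier date through the registration transform — the fusion
behavior that stabilizes segmentation once canopies close.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io_formats import PointCloud


@dataclass
class DensityGrid:
    """Point counts of the xy projection on a regular grid."""

    cell: float
    counts: np.ndarray       # (rows, cols); row 0 at y_min (origin corner)
    origin: tuple[float, float]

    def cell_center(self, row, col):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell
        return x, y


@dataclass
class SegmentationResult:
    plant_id: np.ndarray            # per point, >= 0 or -1 unassigned
    stem_seeds: np.ndarray          # k x 2 world xy
    organ_id: np.ndarray            # per point, 0 stem, 1..k leaves, -1
    provenance: str = "fresh"       # or "guided"


def density_projection(cloud: PointCloud, cell: float = 0.02) -> DensityGrid:
    """Histogram of the cloud's xy coordinates; counts sum to N."""
    if len(cloud) < 1:
        raise ValidationError("cannot project an empty cloud")
    if not (cell > 0):
        raise ValidationError("cell size must be > 0")
    pts = cloud.points
    x0, y0 = float(pts[:, 0].min()), float(pts[:, 1].min())
    ci = np.floor((pts[:, 0] - x0) / cell).astype(int)
    cj = np.floor((pts[:, 1] - y0) / cell).astype(int)
    counts = np.zeros((cj.max() + 1, ci.max() + 1), dtype=np.int64)
    np.add.at(counts, (cj, ci), 1)
    return DensityGrid(cell=float(cell), counts=counts, origin=(x0, y0))


def auto_min_density(grid: DensityGrid) -> float:
    """Seed-density floor: a multiple of the typical occupied-cell count.

    Stem columns concentrate one to two orders of magnitude more projected
    points per cell than leaf surfaces, so a threshold a few times the
    median occupied count passes stems and rejects foliage at any sampling
    density.
    """
    nz = grid.counts[grid.counts > 0]
    if nz.size == 0:
        return 1.0
    return max(5.0, 3.0 * float(np.median(nz)))


def quickshift_seeds(grid: DensityGrid, window: float | None = None,
                     min_density: float | None = None) -> np.ndarray:
    """Density modes of the grid as stem seeds (world xy, k x 2).

    Every cell with count >= ``min_density`` links to its nearest
    strictly-higher-density cell within ``window`` cells (Euclidean); cells
    with no such neighbor are link-tree roots, i.e. local density modes.
    Ties are broken by (row, col) order, making the result deterministic.
    ``window`` defaults to 0.25 m worth of cells (just under the in-row
    plant spacing); ``min_density`` defaults to :func:`auto_min_density`.
    """
    if min_density is None:
        min_density = auto_min_density(grid)
    if window is None:
        window = max(1.0, round(0.25 / grid.cell))
    rows, cols = np.nonzero(grid.counts >= min_density)
    if len(rows) == 0:
        return np.empty((0, 2))
    dens = grid.counts[rows, cols].astype(float)
    rc = np.column_stack([rows, cols]).astype(float)
    # plateau tie-break: among equal counts the lexicographically smaller
    # (row, col) cell ranks higher, so each plateau yields exactly one mode
    lex = rows.astype(np.int64) * (grid.counts.shape[1] + 1) + cols
    seeds = []
    for k in range(len(rows)):
        higher = (dens > dens[k]) | ((dens == dens[k]) & (lex < lex[k]))
        if not higher.any():
            seeds.append(k)
            continue
        d = np.linalg.norm(rc[higher] - rc[k], axis=1)
        if d.min() > window:
            seeds.append(k)
    x, y = grid.cell_center(rows[seeds], cols[seeds])
    return np.column_stack([x, y])


def grow_plants(cloud: PointCloud, seeds: np.ndarray,
                guided_seeds: np.ndarray | None = None,
                guided_transform: np.ndarray | None = None,
                voxel: float = 0.03, max_gap: float = 0.05) -> SegmentationResult:
    """Multi-source region growth from stem-seed columns.

    Every point within ``voxel`` xy-radius of a seed is claimed by its
    nearest seed; the frontier then expands by repeatedly absorbing the
    globally closest unlabeled neighbor within ``max_gap`` (ties broken by
    point index), so contested boundary points go to the nearer plant.
    Points never reached stay -1.  When ``guided_seeds`` are given they
    replace the fresh seeds after the optional 4x4 ``guided_transform``.
    """
    provenance = "fresh"
    if guided_seeds is not None:
        s = np.asarray(guided_seeds, dtype=float).reshape(-1, 2)
        if guided_transform is not None:
            h = np.column_stack([s, np.zeros(len(s)), np.ones(len(s))])
            s = (h @ np.asarray(guided_transform, dtype=float).T)[:, :2]
        seeds = s
        provenance = "guided"
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 2)
    if len(seeds) == 0:
        raise ValidationError("region growth needs at least one seed")
    if len(cloud) == 0:
        raise ValidationError("cannot segment an empty cloud")

    pts = cloud.points
    n = len(pts)
    labels = np.full(n, -1, dtype=np.int64)

    seed_tree = cKDTree(seeds)
    d_seed, nearest_seed = seed_tree.query(pts[:, :2])
    in_column = d_seed <= voxel
    labels[in_column] = nearest_seed[in_column]

    tree = cKDTree(pts)
    pairs = tree.query_pairs(max_gap, output_type="ndarray")
    if len(pairs):
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        gap = np.linalg.norm(pts[src] - pts[dst], axis=1)
        order = np.argsort(src, kind="stable")
        src, dst, gap = src[order], dst[order], gap[order]
        starts = np.searchsorted(src, np.arange(n + 1))
    else:
        dst = np.empty(0, dtype=np.int64)
        gap = np.empty(0)
        starts = np.zeros(n + 1, dtype=np.int64)

    heap: list[tuple[float, int, int]] = []
    for i in np.flatnonzero(in_column):
        lab = int(labels[i])
        for e in range(starts[i], starts[i + 1]):
            j = int(dst[e])
            if labels[j] == -1:
                heapq.heappush(heap, (float(gap[e]), j, lab))
    while heap:
        g, j, lab = heapq.heappop(heap)
        if labels[j] != -1:
            continue
        labels[j] = lab
        for e in range(starts[j], starts[j + 1]):
            k = int(dst[e])
            if labels[k] == -1:
                heapq.heappush(heap, (float(gap[e]), k, lab))

    return SegmentationResult(
        plant_id=labels, stem_seeds=seeds,
        organ_id=np.full(n, -1, dtype=np.int64), provenance=provenance,
    )


def split_stem_leaves(plant_cloud: PointCloud, r_stem: float = 0.04,
                      height_bin: float = 0.05, column_floor: int = 3,
                      link_gap: float = 0.05, min_leaf_points: int = 5
                      ) -> tuple[np.ndarray, bool]:
    """Split one plant's points into stem (0) and leaves (1..k).

    The stem is the vertical column of radius ``r_stem`` around the plant's
    density-mode xy, truncated at the highest height bin whose column count
    stays above ``column_floor``.  Remaining points are clustered by
    connectivity within ``link_gap`` across adjacent height bins; leaf ids
    are ordered by insertion height (lowest = 1).  Plants with < 20 points
    are flagged unsplittable (all organ ids -1).
    """
    n = len(plant_cloud)
    organ = np.full(n, -1, dtype=np.int64)
    if n < 20:
        return organ, False
    pts = plant_cloud.points

    grid = density_projection(plant_cloud, cell=0.02)
    r, c = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
    ax, ay = grid.cell_center(r, c)
    near = np.linalg.norm(pts[:, :2] - [ax, ay], axis=1) <= 0.04
    if near.any():
        ax, ay = pts[near, :2].mean(axis=0)
    axis = np.array([ax, ay])

    radial = np.linalg.norm(pts[:, :2] - axis, axis=1)
    in_col = radial <= r_stem
    z0 = pts[:, 2].min()
    nbins = max(int(math.ceil((pts[:, 2].max() - z0) / height_bin)), 1)
    zbin = np.clip(((pts[:, 2] - z0) / height_bin).astype(int), 0, nbins - 1)
    col_counts = np.bincount(zbin[in_col], minlength=nbins)
    # smooth the column profile and scale the floor to the sampling density:
    # the lower half of the occupied column is certainly stem, so a fraction
    # of its typical bin count separates "stem present" from "leaf crossing"
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(col_counts, kernel, mode="same")
    occ = np.flatnonzero(col_counts > 0)
    if len(occ) == 0:
        top_bin = nbins - 1
    else:
        lower = occ[occ <= occ[0] + max((occ[-1] - occ[0]) // 2, 1)]
        base_level = float(np.median(col_counts[lower]))
        thr = max(float(column_floor) / 3.0, 0.25 * base_level)
        top_bin = occ[0]
        for b in range(occ[0], nbins):
            if smooth[b] >= thr:
                top_bin = b
            else:
                break
    stem = in_col & (zbin <= top_bin)
    organ[stem] = 0

    leaf_idx = np.flatnonzero(~stem)
    if len(leaf_idx) == 0:
        return organ, True
    lp = pts[leaf_idx]
    tree = cKDTree(lp)
    pairs = tree.query_pairs(link_gap, output_type="ndarray")
    parent = np.arange(len(leaf_idx))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    lb = zbin[leaf_idx]
    for a, b in pairs:
        if abs(int(lb[a]) - int(lb[b])) <= 1:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(len(leaf_idx))])
    clusters = {}
    for i, rt in enumerate(roots):
        clusters.setdefault(rt, []).append(i)

    # order clusters by insertion height: z of the member nearest the axis
    ordered, fragments = [], []
    for members in clusters.values():
        members = np.array(members)
        if len(members) < min_leaf_points:
            fragments.append(members)
            continue
        rad = np.linalg.norm(lp[members, :2] - axis, axis=1)
        ins_z = float(lp[members[np.argmin(rad)], 2])
        ordered.append((ins_z, members))
    ordered.sort(key=lambda t: t[0])
    for leaf_id, (_, members) in enumerate(ordered, start=1):
        organ[leaf_idx[members]] = leaf_id
    # absorb small fragments into the nearest retained leaf, if close enough
    if ordered and fragments:
        kept = np.flatnonzero(organ[leaf_idx] > 0)
        kt = cKDTree(lp[kept])
        for members in fragments:
            d, j = kt.query(lp[members])
            if d.min() <= 2 * link_gap:
                organ[leaf_idx[members]] = organ[leaf_idx[kept[j[np.argmin(d)]]]]
    return organ, True


def segment_population(cloud: PointCloud, cell: float = 0.02,
                       window: float | None = None,
                       min_density: float | None = None,
                       guided_seeds: np.ndarray | None = None,
                       guided_transform: np.ndarray | None = None,
                       voxel: float = 0.03, max_gap: float = 0.05,
                       split_organs: bool = True) -> SegmentationResult:
    """Full segmentation: seeds -> plants -> stems and leaves."""
    grid = density_projection(cloud, cell=cell)
    seeds = quickshift_seeds(grid, window=window, min_density=min_density)
    if guided_seeds is None and len(seeds) == 0:
        raise ValidationError("no stem seeds found; lower min_density")
    result = grow_plants(cloud, seeds, guided_seeds=guided_seeds,
                         guided_transform=guided_transform,
                         voxel=voxel, max_gap=max_gap)
    if split_organs:
        for pid in np.unique(result.plant_id):
            if pid < 0:
                continue
            idx = np.flatnonzero(result.plant_id == pid)
            organ, _ = split_stem_leaves(cloud.select(idx))
            result.organ_id[idx] = organ
    return result


def label_accuracy(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Per-point accuracy under one-to-one cluster-to-truth matching.

    Predicted clusters are assigned to truth labels greedily by overlap,
    each side used at most once, so both merges and splits cost accuracy
    (a split plant duplicates phenotype records; a merged pair loses one).
    Unassigned (-1) predictions never count as correct.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValidationError("label arrays must have equal length")
    overlaps = []
    for lab in np.unique(predicted):
        if lab < 0:
            continue
        m = predicted == lab
        for t in np.unique(truth[m]):
            if t < 0:
                continue
            overlaps.append((int(np.sum(truth[m] == t)), int(lab), int(t)))
    overlaps.sort(reverse=True)
    used_p, used_t = set(), set()
    correct = 0
    for n, lab, t in overlaps:
        if lab in used_p or t in used_t:
            continue
        used_p.add(lab)
        used_t.add(t)
        correct += n
    return correct / max(len(truth), 1)
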