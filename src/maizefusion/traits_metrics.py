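"""Structural trait extraction and accuracy assessment.

Traits per plant: height (high-percentile z above the ground datum) and
crown size (xy convex-hull area).  Traits per leaf: inclination (angle of
the midrib chord to the horizontal, folded into [0, 90] degrees), azimuth
(bearing of the chord's xy projection, counterclockwise from +x in
[0, 360)), and length (polyline length of the binned midrib).

Assessment compares estimated against reference values with the
coefficient of determination R^2 = 1 - SS_res / SS_tot, MSE, RMSE and MAE,
all in the standard error forms on (v, v'); azimuths are compared on the
circle with wrapped differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .io_formats import PointCloud, TraitTable
from .plant_segmentation import SegmentationResult, density_projection


@dataclass
class EvaluationReport:
    m: int
    r_squared: float
    mse: float
    rmse: float
    mae: float
    pairs: pd.DataFrame          # columns: key fields, reference, estimated
    unmatched_reference: int = 0
    unmatched_estimated: int = 0
    zero_variance: bool = False


# ---------------------------------------------------------------------------
# per-plant / per-leaf traits
# ---------------------------------------------------------------------------


def plant_height(plant_cloud: PointCloud, ground_level: float = 0.0,
                 percentile: float = 99.0) -> float:
    """Height of the percentile-th z above the ground datum (m).

    The default 99th percentile is robust to stray high points left by
    registration or segmentation errors.
    """
    if len(plant_cloud) == 0:
        raise ValidationError("empty plant cloud")
    return float(np.percentile(plant_cloud.points[:, 2], percentile) - ground_level)


def leaf_angles(leaf_cloud: PointCloud, stem_axis_xy) -> tuple[float, float]:
    """(inclination deg in [0, 90], azimuth deg in [0, 360)) of the midrib chord.

    The chord runs from the leaf's innermost point (nearest the stem axis in
    xy) to its outermost point.  Returns (nan, nan) for leaves with fewer
    than 5 points.
    """
    if len(leaf_cloud) < 5:
        return float("nan"), float("nan")
    pts = leaf_cloud.points
    axis = np.asarray(stem_axis_xy, dtype=float).reshape(2)
    radial = np.linalg.norm(pts[:, :2] - axis, axis=1)
    inner = pts[np.argmin(radial)]
    outer = pts[np.argmax(radial)]
    chord = outer - inner
    horiz = math.hypot(chord[0], chord[1])
    inclination = abs(math.degrees(math.atan2(chord[2], horiz)))
    azimuth = math.degrees(math.atan2(chord[1], chord[0])) % 360.0
    return inclination, azimuth


def crown_size(plant_cloud: PointCloud) -> tuple[float, bool]:
    """xy convex-hull area (m^2); degenerate inputs give (0, flagged)."""
    if len(plant_cloud) < 3:
        return 0.0, False
    try:
        hull = ConvexHull(plant_cloud.points[:, :2])
        return float(hull.volume), True      # 2D hull: volume is the area
    except QhullError:
        return 0.0, False


def leaf_length(leaf_cloud: PointCloud, stem_axis_xy,
                bin_width: float = 0.02) -> float:
    """Midrib polyline length (m): bin points by radial distance from the
    stem axis, take per-bin 3D centroids, sum consecutive centroid gaps.

    Returns nan below 5 points and 0 when all points fall in one bin.
    """
    if len(leaf_cloud) < 5:
        return float("nan")
    pts = leaf_cloud.points
    axis = np.asarray(stem_axis_xy, dtype=float).reshape(2)
    radial = np.linalg.norm(pts[:, :2] - axis, axis=1)
    bins = np.floor((radial - radial.min()) / bin_width).astype(int)
    centroids = [pts[np.argmin(radial)]]       # innermost point anchors the base
    for b in np.unique(bins):
        centroids.append(pts[bins == b].mean(axis=0))
    centroids.append(pts[np.argmax(radial)])   # outermost point anchors the tip
    if len(np.unique(bins)) < 2:
        return 0.0
    centroids = np.array(centroids)
    return float(np.linalg.norm(np.diff(centroids, axis=0), axis=1).sum())


def local_ground_function(ground_cloud: PointCloud, radius: float = 0.2):
    """Terrain elevation query from the classified ground points.

    Returns a callable (x, y) -> median z of the ground points within
    ``radius``; falls back to the nearest ground point when the disc is
    empty.
    """
    from scipy.spatial import cKDTree

    if len(ground_cloud) == 0:
        raise ValidationError("no ground points to build a terrain model")
    pts = ground_cloud.points
    tree = cKDTree(pts[:, :2])

    def level(x, y):
        idx = tree.query_ball_point([x, y], radius)
        if not idx:
            _, j = tree.query([x, y])
            return float(pts[j, 2])
        return float(np.median(pts[idx, 2]))

    return level


def stem_axis_of(plant_cloud: PointCloud, organ: np.ndarray | None = None) -> np.ndarray:
    """Stem axis xy: mean of stem points, else the plant's density-mode cell."""
    if organ is not None and (organ == 0).any():
        return plant_cloud.points[organ == 0, :2].mean(axis=0)
    grid = density_projection(plant_cloud, cell=0.02)
    r, c = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
    x, y = grid.cell_center(r, c)
    return np.array([float(x), float(y)])


def extract_traits(cloud: PointCloud, segmentation: SegmentationResult,
                   date_tag: str = "d1", ground_level=0.0,
                   height_percentile: float = 99.0) -> TraitTable:
    """Trait table for a segmented population cloud.

    ``ground_level`` is either a scalar elevation or a callable
    ``(x, y) -> z`` giving the local terrain elevation (heights are then
    measured from the ground under each plant's stem axis).
    """
    records = []
    for pid in np.unique(segmentation.plant_id):
        if pid < 0:
            continue
        idx = np.flatnonzero(segmentation.plant_id == pid)
        plant = cloud.select(idx)
        organ = segmentation.organ_id[idx]
        axis0 = stem_axis_of(plant, organ)
        gl = ground_level(*axis0) if callable(ground_level) else ground_level
        records.append((date_tag, int(pid), -1, "plant_height",
                        plant_height(plant, ground_level=float(gl),
                                     percentile=height_percentile), "m"))
        area, _ = crown_size(plant)
        records.append((date_tag, int(pid), -1, "crown_size", area, "m2"))
        axis = axis0
        for oid in np.unique(organ):
            if oid < 1:
                continue
            leaf = plant.select(organ == oid)
            inc, azi = leaf_angles(leaf, axis)
            if math.isnan(inc):
                continue
            length = leaf_length(leaf, axis)
            records.append((date_tag, int(pid), int(oid), "leaf_inclination", inc, "deg"))
            records.append((date_tag, int(pid), int(oid), "leaf_azimuth", azi, "deg"))
            if not math.isnan(length):
                records.append((date_tag, int(pid), int(oid), "leaf_length", length, "m"))
    if not records:
        return TraitTable.empty()
    return TraitTable.from_records(records)


# ---------------------------------------------------------------------------
# assessment
# ---------------------------------------------------------------------------


def wrapped_difference(a, b, period: float = 360.0):
    """Signed circular difference a - b folded into (-period/2, period/2]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2, d - period, d)


def _circular_mean(deg):
    rad = np.radians(np.asarray(deg, dtype=float))
    return math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0


def regression_metrics(reference, estimated, circular: bool = False):
    """(r_squared, mse, rmse, mae, zero_variance_flag) between two vectors."""
    v = np.asarray(reference, dtype=float)
    vp = np.asarray(estimated, dtype=float)
    if v.shape != vp.shape or v.size < 2:
        raise ValidationError("need >= 2 paired values")
    if circular:
        err = wrapped_difference(vp, v)
        dev = wrapped_difference(v, _circular_mean(v))
    else:
        err = vp - v
        dev = v - v.mean()
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum(dev**2))
    if ss_tot <= 0:
        return float("nan"), mse, rmse, mae, True
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return r2, mse, rmse, mae, False


def evaluate(reference: TraitTable, estimated: TraitTable, trait_name: str,
             circular: bool | None = None) -> EvaluationReport:
    """Score estimated against reference values of one trait.

    Pairs are matched on (date_tag, plant_id, organ_id); unmatched keys are
    counted, not scored.  ``circular`` defaults to True for azimuth traits.
    """
    if circular is None:
        circular = "azimuth" in trait_name
    ref = reference.filter(trait_name=trait_name)
    est = estimated.filter(trait_name=trait_name)
    merged = ref.merge(est, on=["date_tag", "plant_id", "organ_id"],
                       suffixes=("_ref", "_est"))
    if len(merged) < 2:
        raise ValidationError(
            f"need >= 2 matched pairs for {trait_name!r}, got {len(merged)}"
        )
    r2, mse, rmse, mae, zero_var = regression_metrics(
        merged["value_ref"], merged["value_est"], circular=circular
    )
    pairs = merged[["date_tag", "plant_id", "organ_id", "value_ref", "value_est"]]
    return EvaluationReport(
        m=len(merged), r_squared=r2, mse=mse, rmse=rmse, mae=mae, pairs=pairs,
        unmatched_reference=len(ref) - len(merged),
        unmatched_estimated=len(est) - len(merged),
        zero_variance=zero_var,
    )
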