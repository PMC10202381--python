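"""Direct linear transformation between image plane and point-cloud space,
feature matching, and time-series cloud registration.

The DLT relates a 2D image point (x, y) to a 3D point (X, Y, Z) through 11
coefficients l1..l11:

    x + (l1 X + l2 Y + l3 Z + l4) / (l9 X + l10 Y + l11 Z + 1) = 0
    y + (l5 X + l6 Y + l7 Z + l8) / (l9 X + l10 Y + l11 Z + 1) = 0

With n correspondences this expands into a stacked 2n x 11 linear system
B L = W with error equation V = B L - W, solved as weighted least squares
L = (B' P B)^-1 B' P W through a numerically stable factorization.  Six
correspondences are the solvability minimum (12 equations for 11 unknowns);
the operational gate defaults to 12 matched points.

Because the signs above follow the source equations literally, the forward
projection is x = -(l1 X + l2 Y + l3 Z + l4) / (l9 X + l10 Y + l11 Z + 1);
``DLTModel.camera_matrix`` exposes the conventional-sign 3x4 camera.

Top-view acquisitions are nearly orthographic, which can leave the
denominator terms l9..l11 unidentifiable; when the design matrix condition
number exceeds a threshold the model is refit with l9 = l10 = l11 = 0 (an
8-parameter affine camera) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    MaizeFusionError,
    InsufficientCorrespondencesError,
    RegistrationQualityError,
    ValidationError,
)
from .io_formats import OrthoImage, PointCloud
from .ortho_features import (
    FeatureSet,
    PlanarTransform,
    _mutual_nearest,
    _similarity_from_pairs,
    align_images,
    binarize_vegetation,
    chain_to_reference,
    extract_features,
)
from .synthetic_scene import SOIL_COLOR, apply_transform, make_rigid_scale

HARD_MIN_CORRESPONDENCES = 6   # 12 equations >= 11 unknowns
DEFAULT_MIN_MATCHES = 12       # operational gate: > 11 matched points


@dataclass
class Correspondence:
    """One matched (image 2D <-> cloud 3D) feature-point pair."""

    image_xy: np.ndarray
    cloud_xyz: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.image_xy = np.asarray(self.image_xy, dtype=float).reshape(2)
        self.cloud_xyz = np.asarray(self.cloud_xyz, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.image_xy)) and np.all(np.isfinite(self.cloud_xyz))):
            raise ValidationError("correspondence coordinates must be finite")
        if not (self.weight > 0):
            raise ValidationError("correspondence weight must be > 0")


@dataclass
class DLTModel:
    """Fitted 11-coefficient model with its stacked linear system."""

    L: np.ndarray                  # 11 coefficients
    B: np.ndarray                  # 2n x 11 design
    W: np.ndarray                  # 2n observations
    P: np.ndarray                  # 2n weights (diagonal of the weight matrix)
    V: np.ndarray                  # residuals, V = B L - W exactly as stored
    rms_reprojection: float
    condition_number: float
    degenerate_geometry: bool = False
    correspondences: list[Correspondence] = field(default_factory=list)

    def project(self, xyz: np.ndarray) -> np.ndarray:
        """Image (x, y) predicted for 3D points (literal-sign forward map)."""
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        l = self.L
        den = xyz @ l[8:11] + 1.0
        x = -(xyz @ l[0:3] + l[3]) / den
        y = -(xyz @ l[4:7] + l[7]) / den
        return np.column_stack([x, y])

    def camera_matrix(self) -> np.ndarray:
        """Conventional-sign 3x4 camera: (x, y) ~ M [X Y Z 1]'."""
        l = self.L
        return np.array([
            [-l[0], -l[1], -l[2], -l[3]],
            [-l[4], -l[5], -l[6], -l[7]],
            [l[8], l[9], l[10], 1.0],
        ])


@dataclass
class RigidScaleTransform3D:
    """z-rotation + uniform scale + 3D translation applied to clouds."""

    rotation: float
    scale: float
    translation: np.ndarray
    residual: float = float("nan")

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValidationError("scale must be > 0")
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidScaleTransform3D":
        return cls(rotation=0.0, scale=1.0, translation=np.zeros(3))

    def matrix(self) -> np.ndarray:
        return make_rigid_scale(self.rotation, self.scale, self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(points, self.matrix())

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "RigidScaleTransform3D":
        scale = float(np.linalg.norm(T[:2, 0]))
        rot = float(math.atan2(T[1, 0], T[0, 0]))
        return cls(rotation=rot, scale=scale, translation=T[:3, 3].copy())

    def inverse(self) -> "RigidScaleTransform3D":
        return self.from_matrix(np.linalg.inv(self.matrix()))


# ---------------------------------------------------------------------------
# cloud projection and matching
# ---------------------------------------------------------------------------


def estimate_ground_level(z: np.ndarray, bin_width: float = 0.02,
                          search_band: float = 0.6) -> float:
    """Terrain elevation estimate: median z inside the densest low bin.

    Looks for the modal height bin within ``search_band`` of the lowest
    point (the bare-soil return dominates there), then refines with the
    median of points within one bin of that mode.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValidationError("cannot estimate ground level of an empty cloud")
    lo = float(z.min())
    edges = np.arange(lo, lo + search_band + bin_width, bin_width)
    counts, _ = np.histogram(z, bins=edges)
    k = int(np.argmax(counts))
    center = 0.5 * (edges[k] + edges[k + 1])
    near = z[np.abs(z - center) <= 1.5 * bin_width]
    return float(np.median(near)) if near.size else center


def project_cloud(cloud: PointCloud, gsd: float,
                  contour_samples_per_component: int = 8,
                  min_component_px: int = 30) -> tuple[OrthoImage, FeatureSet]:
    """Parallel (z-axis) projection of the cloud plus its feature points.

    Rasterizes occupancy at ``gsd`` (top-most point wins the pixel color),
    runs the same binarize/extract pipeline as for camera orthomosaics, and
    attaches to every keypoint the 3D coordinate of the cloud point nearest
    to it in xy, so downstream matches yield (x, y) <-> (X, Y, Z) pairs.
    """
    if len(cloud) == 0:
        raise ValidationError("cannot project an empty cloud")
    if not (gsd > 0):
        raise ValidationError("gsd must be > 0")
    pts = cloud.points
    x_min, y_max = pts[:, 0].min(), pts[:, 1].max()
    W = int(np.ceil((pts[:, 0].max() - x_min) / gsd)) + 1
    H = int(np.ceil((y_max - pts[:, 1].min()) / gsd)) + 1

    c = np.clip(np.round((pts[:, 0] - x_min) / gsd).astype(int), 0, W - 1)
    r = np.clip(np.round((y_max - pts[:, 1]) / gsd).astype(int), 0, H - 1)
    if cloud.colors is not None:
        colors = cloud.colors
    else:
        # colorless clouds: paint by height above the terrain estimate
        gl = estimate_ground_level(pts[:, 2])
        green = pts[:, 2] > gl + 0.05
        colors = np.where(green[:, None],
                          np.array([[44, 160, 44]], dtype=np.uint8),
                          np.array([SOIL_COLOR], dtype=np.uint8))
    # splat radius ~ the cloud's median xy point spacing so the raster is
    # contiguous even when gsd is finer than the sampling density
    xy_tree = cKDTree(pts[:, :2])
    sample = pts[:: max(len(pts) // 4000, 1), :2]
    nn = xy_tree.query(sample, k=2)[0][:, 1]
    radius = int(np.clip(np.ceil(0.55 * np.median(nn) / gsd), 1, 4))
    order = np.argsort(pts[:, 2], kind="stable")  # top points painted last
    img = np.zeros((H, W, 3), dtype=np.uint8)
    ro, co, colo = r[order], c[order], colors[order]
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            rr = ro + dr
            cc = co + dc
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            img[rr[ok], cc[ok]] = colo[ok]

    image = OrthoImage(pixels=img, gsd=gsd, origin=(float(x_min), float(y_max)),
                       date_tag=cloud.date_tag)
    mask = binarize_vegetation(image)
    feats = extract_features(mask, image,
                             contour_samples_per_component=contour_samples_per_component,
                             min_component_px=min_component_px)
    feats.source = "cloud_projection"
    if len(feats):
        tree = cKDTree(pts[:, :2])
        _, idx = tree.query(feats.keypoints)
        # keypoint xy is already in the cloud frame (parallel projection);
        # the nearest cloud point supplies the height coordinate
        feats.cloud_xyz = np.column_stack([feats.keypoints, pts[idx, 2]])
    else:
        feats.cloud_xyz = np.empty((0, 3))
    return image, feats


def match_features(image_feats: FeatureSet, cloud_feats: FeatureSet,
                   coarse: PlanarTransform | None = None,
                   max_dist: float = 0.1,
                   marker_weight: float = 4.0) -> list[Correspondence]:
    """Mutual-nearest one-to-one pairing of image and cloud feature points.

    ``coarse`` (typically from ``align_images`` on the two centroid sets)
    pre-transforms the cloud keypoints; matched pairs carry the cloud
    keypoint's attached 3D coordinate.  Calibration-marker pairs get
    ``marker_weight`` (markers are exact landmarks in both sensors).  May
    return an empty list.
    """
    if len(image_feats) == 0 or len(cloud_feats) == 0:
        return []
    if cloud_feats.cloud_xyz is None:
        raise ValidationError("cloud feature set lacks attached 3D coordinates")
    cpts = cloud_feats.keypoints
    if coarse is not None:
        cpts = coarse.apply(cpts)
    pairs = _mutual_nearest(image_feats.keypoints, cpts, max_dist)
    out = []
    for i, j in pairs:
        w = (marker_weight
             if image_feats.kinds[i] == "marker" == cloud_feats.kinds[j]
             else 1.0)
        out.append(Correspondence(image_xy=image_feats.keypoints[i],
                                  cloud_xyz=cloud_feats.cloud_xyz[j],
                                  weight=w))
    return out


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def build_dlt_system(correspondences: list[Correspondence]):
    """Stacked (B, W, P) of the expanded linear system, two rows per point."""
    n = len(correspondences)
    B = np.zeros((2 * n, 11))
    W = np.zeros(2 * n)
    P = np.ones(2 * n)
    for k, corr in enumerate(correspondences):
        x, y = corr.image_xy
        X, Y, Z = corr.cloud_xyz
        B[2 * k] = [X, Y, Z, 1.0, 0, 0, 0, 0, x * X, x * Y, x * Z]
        B[2 * k + 1] = [0, 0, 0, 0, X, Y, Z, 1.0, y * X, y * Y, y * Z]
        W[2 * k] = -x
        W[2 * k + 1] = -y
        P[2 * k] = P[2 * k + 1] = corr.weight
    return B, W, P


def estimate_dlt(correspondences: list[Correspondence],
                 min_matches: int = DEFAULT_MIN_MATCHES,
                 condition_threshold: float = 1e7) -> DLTModel:
    """Weighted least-squares fit of the 11 DLT coefficients.

    Raises :class:`InsufficientCorrespondencesError` below the gate
    (``max(6, min_matches)`` pairs) and falls back to the 8-parameter affine
    camera (flagged) when the full system is ill-conditioned.
    """
    needed = max(HARD_MIN_CORRESPONDENCES, int(min_matches))
    if len(correspondences) < needed:
        raise InsufficientCorrespondencesError(needed, len(correspondences))

    B, W, P = build_dlt_system(correspondences)
    sqp = np.sqrt(P)[:, None]
    A = B * sqp
    b = W * sqp[:, 0]
    sv = np.linalg.svd(A, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")

    degenerate = not np.isfinite(cond) or cond > condition_threshold
    if not degenerate:
        L = np.linalg.lstsq(A, b, rcond=None)[0]
    else:
        # near-orthographic geometry: denominator terms unidentifiable
        A8 = A[:, :8]
        sv8 = np.linalg.svd(A8, compute_uv=False)
        if sv8[-1] <= max(A8.shape) * np.finfo(float).eps * sv8[0]:
            raise DegenerateGeometryError(
                "correspondence geometry is rank deficient even for the "
                f"affine camera (smallest singular value {sv8[-1]:.3e})"
            )
        L = np.zeros(11)
        L[:8] = np.linalg.lstsq(A8, b, rcond=None)[0]

    V = B @ L - W
    model = DLTModel(L=L, B=B, W=W, P=P, V=V, rms_reprojection=0.0,
                     condition_number=cond, degenerate_geometry=degenerate,
                     correspondences=list(correspondences))
    obs = np.array([c.image_xy for c in correspondences])
    pred = model.project(np.array([c.cloud_xyz for c in correspondences]))
    model.rms_reprojection = float(
        np.sqrt(np.mean(np.sum((pred - obs) ** 2, axis=1)))
    )
    return model


def solve_normal_equations(B: np.ndarray, W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Explicit L = (B' P B)^-1 B' P W (reference route, not the solver)."""
    Pm = np.diag(P)
    return np.linalg.solve(B.T @ Pm @ B, B.T @ Pm @ W)


# ---------------------------------------------------------------------------
# applying the registration
# ---------------------------------------------------------------------------


def register_cloud(cloud: PointCloud, model: DLTModel,
                   reference_frame: str = "world",
                   rms_threshold: float = 0.05,
                   reference_ground_z: float = 0.0
                   ) -> tuple[PointCloud, RigidScaleTransform3D]:
    """Move a cloud into the image frame using a fitted DLT.

    The in-plane rotation, uniform scale and xy translation are extracted by
    fitting a 2D similarity between the correspondences' cloud (X, Y) and
    their DLT-projected image (x, y); z is preserved up to the same scale
    with an offset that brings the cloud's estimated terrain elevation to
    ``reference_ground_z``.
    """
    if model.rms_reprojection > rms_threshold:
        raise RegistrationQualityError(
            f"model rms {model.rms_reprojection:.4f} m exceeds threshold "
            f"{rms_threshold:.4f} m"
        )
    if not model.correspondences:
        raise ValidationError("model carries no correspondences")
    xyz = np.array([c.cloud_xyz for c in model.correspondences])
    pred = model.project(xyz)
    sim = _similarity_from_pairs(xyz[:, :2], pred)
    if sim is None:
        raise RegistrationQualityError("correspondences collapse to a point")

    z_scaled = cloud.points[:, 2] * sim.scale
    tz = reference_ground_z - estimate_ground_level(z_scaled)
    transform = RigidScaleTransform3D(
        rotation=sim.rotation, scale=sim.scale,
        translation=np.array([sim.translation[0], sim.translation[1], tz]),
    )
    new_pts = transform.apply(cloud.points)
    moved = transform.apply(xyz)[:, :2]
    obs = np.array([c.image_xy for c in model.correspondences])
    transform.residual = float(
        np.sqrt(np.mean(np.sum((moved - obs) ** 2, axis=1)))
    )
    return cloud.with_points(new_pts, frame_id=reference_frame), transform


def register_time_series(scenes: list[tuple[PointCloud, OrthoImage]],
                         min_matches: int = DEFAULT_MIN_MATCHES,
                         max_match_dist: float = 0.12,
                         rms_threshold: float = 0.05,
                         contour_samples: int = 8,
                         min_component_px: int = 30,
                         seed: int = 0):
    """Register every date's cloud into date 1's image frame.

    Images are chained date-to-date with the robust similarity consensus;
    each date's cloud is matched to its (reference-frame) image features,
    a DLT is fit, and the implied rigid+scale transform applied.  Failures
    are isolated per date: earlier successes are still returned.

    Returns (registered clouds (None where failed), transforms, report).
    """
    if len(scenes) < 1:
        raise ValidationError("need at least one date")

    image_feats = []
    for cloud, image in scenes:
        mask = binarize_vegetation(image)
        image_feats.append(extract_features(
            mask, image, contour_samples_per_component=contour_samples,
            min_component_px=min_component_px))

    pair_transforms = []
    for d in range(1, len(scenes)):
        prev_mk = image_feats[d - 1].of_kind("marker")
        cur_mk = image_feats[d].of_kind("marker")
        if len(prev_mk) >= 3 and len(cur_mk) >= 3:
            # calibration objects pin the inter-date image alignment
            pair_transforms.append(
                align_images(prev_mk, cur_mk, inlier_tol=0.05,
                             max_rotation=math.radians(25.0),
                             rng=seed + 13 * d))
        else:
            pair_transforms.append(
                align_images(image_feats[d - 1], image_feats[d],
                             inlier_tol=0.05,
                             max_rotation=math.radians(25.0),
                             rng=seed + 13 * d))
    chain = chain_to_reference(pair_transforms)

    registered: list[PointCloud | None] = []
    transforms: list[RigidScaleTransform3D | None] = []
    report = []
    reference_ground = None
    for d, (cloud, image) in enumerate(scenes):
        entry = {"date_tag": cloud.date_tag or f"d{d + 1}", "status": "ok"}
        try:
            feats_ref = FeatureSet(
                keypoints=chain[d].apply(image_feats[d].keypoints),
                kinds=image_feats[d].kinds, source="ortho_image",
                date_tag=image_feats[d].date_tag,
            )
            _, cloud_feats = project_cloud(
                cloud, image.gsd, contour_samples_per_component=contour_samples,
                min_component_px=min_component_px)
            img_cm = feats_ref.of_kind("centroid", "marker")
            cld_cm = cloud_feats.of_kind("centroid", "marker")
            # calibration markers anchor the coarse alignment whenever both
            # sides see at least 3: canopy blobs on a regular planting grid
            # carry a shift-by-one-plant ambiguity that markers break
            img_mk = feats_ref.of_kind("marker")
            cld_mk = cloud_feats.of_kind("marker")
            if len(img_mk) >= 3 and len(cld_mk) >= 3:
                coarse = align_images(img_mk, cld_mk, inlier_tol=0.05,
                                      max_rotation=math.radians(25.0),
                                      rng=seed + 31 * d)
            else:
                coarse = align_images(img_cm, cld_cm, inlier_tol=0.05,
                                      max_rotation=math.radians(25.0),
                                      rng=seed + 31 * d)
            # centroids and markers are phase-free landmarks; contour samples
            # have arbitrary phase along the boundary, so they only join as
            # down-weighted extras when closed canopies leave too few blobs
            corrs = match_features(img_cm, cld_cm, coarse=coarse,
                                   max_dist=max_match_dist)
            needed = max(HARD_MIN_CORRESPONDENCES, min_matches)
            if len(corrs) < needed:
                extra = match_features(
                    feats_ref.of_kind("contour_sample"),
                    cloud_feats.of_kind("contour_sample"),
                    coarse=coarse, max_dist=0.06)
                for c in extra:
                    c.weight = 0.3
                corrs = corrs + extra
            model = estimate_dlt(corrs, min_matches=min_matches)
            ref_gz = 0.0 if reference_ground is None else reference_ground
            if reference_ground is None:
                # date 1 sets the vertical datum for the whole series
                ref_gz = estimate_ground_level(cloud.points[:, 2])
            reg, transform = register_cloud(
                cloud, model, reference_frame="date1",
                rms_threshold=rms_threshold, reference_ground_z=ref_gz)
            # refinement pass: re-project the registered cloud and re-match
            # at a tight radius, where pairing is unambiguous
            try:
                _, feats2 = project_cloud(
                    reg, image.gsd,
                    contour_samples_per_component=contour_samples,
                    min_component_px=min_component_px)
                corrs2 = match_features(feats_ref.of_kind("centroid", "marker"),
                                        feats2.of_kind("centroid", "marker"),
                                        max_dist=0.05)
                model2 = estimate_dlt(corrs2, min_matches=min_matches)
                reg2, t2 = register_cloud(
                    reg, model2, reference_frame="date1",
                    rms_threshold=rms_threshold, reference_ground_z=ref_gz)
                if len(corrs2) >= len(corrs) and t2.residual <= transform.residual:
                    reg = reg2
                    transform = RigidScaleTransform3D.from_matrix(
                        t2.matrix() @ transform.matrix())
                    transform.residual = t2.residual
                    corrs, model = corrs2, model2
            except MaizeFusionError:
                pass  # keep the first-pass result
            if reference_ground is None:
                reference_ground = estimate_ground_level(reg.points[:, 2])
            registered.append(reg)
            transforms.append(transform)
            entry.update(
                n_matches=len(corrs), dlt_rms=model.rms_reprojection,
                condition_number=model.condition_number,
                degenerate=model.degenerate_geometry,
                rotation_deg=math.degrees(transform.rotation),
                scale=transform.scale,
                translation=transform.translation.tolist(),
                residual=transform.residual,
            )
        except Exception as exc:  # isolate per-date failures
            registered.append(None)
            transforms.append(None)
            entry.update(status="failed", error=f"{type(exc).__name__}: {exc}")
        report.append(entry)
    return registered, transforms, report
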