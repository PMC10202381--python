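"""Vegetation binarization, contour/centroid feature extraction and
inter-date image alignment.

Plant pixels are separated from soil with the excess-green index
(2G - R - B) thresholded by Otsu's method, followed by a 3x3 morphological
opening and hole filling.  Each sufficiently large connected component
contributes one area centroid and k equally spaced boundary samples as
feature points (in world meters).  Images from different dates are aligned
by a robust 2-point similarity consensus over the feature sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import InsufficientFeaturesError, RegistrationFailureError, ValidationError
from .io_formats import OrthoImage

KIND_CENTROID = "centroid"
KIND_CONTOUR = "contour_sample"
KIND_MARKER = "marker"


@dataclass
class FeatureSet:
    """2D keypoints (world meters) with per-point kinds."""

    keypoints: np.ndarray               # n x 2
    kinds: np.ndarray                   # n, dtype object/str
    source: str = "ortho_image"         # or "cloud_projection"
    date_tag: str = ""
    border_flags: np.ndarray | None = None
    cloud_xyz: np.ndarray | None = None  # n x 3, set for cloud projections

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64).reshape(-1, 2)
        if not np.all(np.isfinite(self.keypoints)):
            raise ValidationError("keypoints must be finite")
        self.kinds = np.asarray(self.kinds, dtype=object).reshape(-1)
        if len(self.kinds) != len(self.keypoints):
            raise ValidationError("kinds length mismatch")
        bad = set(self.kinds) - {KIND_CENTROID, KIND_CONTOUR, KIND_MARKER}
        if bad:
            raise ValidationError(f"invalid keypoint kinds {bad}")

    def __len__(self):
        return len(self.keypoints)

    def of_kind(self, *kinds) -> "FeatureSet":
        m = np.isin(self.kinds, kinds)
        return FeatureSet(
            keypoints=self.keypoints[m], kinds=self.kinds[m], source=self.source,
            date_tag=self.date_tag,
            border_flags=None if self.border_flags is None else self.border_flags[m],
            cloud_xyz=None if self.cloud_xyz is None else self.cloud_xyz[m],
        )


@dataclass
class PlanarTransform:
    """2D similarity p' = scale * R(rotation) p + translation."""

    rotation: float
    scale: float
    translation: np.ndarray
    inlier_count: int = 0
    rms_residual: float = 0.0

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValidationError("scale must be > 0")
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(rotation=0.0, scale=1.0, translation=np.zeros(2))

    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ self.matrix().T + self.translation

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """self after other: x -> self(other(x))."""
        return PlanarTransform(
            rotation=self.rotation + other.rotation,
            scale=self.scale * other.scale,
            translation=self.matrix() @ other.translation + self.translation,
        )

    def inverse(self) -> "PlanarTransform":
        inv_m = np.linalg.inv(self.matrix())
        return PlanarTransform(
            rotation=-self.rotation, scale=1.0 / self.scale,
            translation=-inv_m @ self.translation,
        )


# ---------------------------------------------------------------------------
# binarization and feature extraction
# ---------------------------------------------------------------------------


def binarize_vegetation(image: OrthoImage) -> np.ndarray:
    """Excess-green + Otsu vegetation mask, opened and hole-filled.

    A degenerate (uniform excess-green) image yields an all-zero mask with a
    warning rather than an exception.
    """
    px = image.pixels.astype(np.int32)
    exg = 2 * px[:, :, 1] - px[:, :, 0] - px[:, :, 2]
    if exg.max() == exg.min():
        warnings.warn("uniform image: vegetation mask is empty", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    thr = threshold_otsu(exg)
    # Otsu on a soil/canopy mixture can land below zero excess green when
    # vegetation dominates; never call negative excess green vegetation.
    mask = exg > max(thr, 0)
    if not mask.any():
        warnings.warn("no vegetation above Otsu threshold", stacklevel=2)
        return mask
    mask = morphology.opening(mask, morphology.footprint_rectangle((3, 3)))
    from scipy.ndimage import binary_fill_holes

    return binary_fill_holes(mask)


def _component_features(mask, image, contour_samples, min_component_px, kind):
    lab = measure.label(mask, connectivity=2)
    pts, kinds, border = [], [], []
    H, W = mask.shape
    for region in measure.regionprops(lab):
        if region.area < min_component_px:
            continue
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == H or c1 == W
        rc, cc = region.centroid
        x, y = image.pixel_to_world(rc, cc)
        pts.append((x, y))
        kinds.append(kind)
        border.append(touches)
        if contour_samples > 0:
            comp = lab == region.label
            contours = measure.find_contours(comp.astype(float), 0.5)
            if contours:
                contour = max(contours, key=len)
                # arc-length-uniform boundary samples
                seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
                s = np.r_[0.0, np.cumsum(seg)]
                if s[-1] > 0:
                    targets = np.linspace(0, s[-1], contour_samples, endpoint=False)
                    idx = np.searchsorted(s, targets)
                    for r, c in contour[np.clip(idx, 0, len(contour) - 1)]:
                        xs, ys = image.pixel_to_world(r, c)
                        pts.append((float(xs), float(ys)))
                        kinds.append(KIND_CONTOUR)
                        border.append(touches)
    return pts, kinds, border


def extract_features(mask: np.ndarray, image_meta: OrthoImage,
                     contour_samples_per_component: int = 8,
                     min_component_px: int = 30,
                     detect_markers: bool = True) -> FeatureSet:
    """Centroids + equally spaced boundary samples of each large component.

    White calibration squares (all channels bright) are detected from the
    source image and added as marker keypoints.
    """
    pts, kinds, border = _component_features(
        mask, image_meta, contour_samples_per_component, min_component_px,
        KIND_CENTROID,
    )
    if detect_markers:
        white = np.all(image_meta.pixels > 220, axis=2) & ~mask
        if white.any():
            mpts, mkinds, mborder = _component_features(
                white, image_meta, 0, min_component_px, KIND_MARKER
            )
            pts += mpts
            kinds += mkinds
            border += mborder
    if not pts:
        return FeatureSet(
            keypoints=np.empty((0, 2)), kinds=np.empty(0, dtype=object),
            date_tag=image_meta.date_tag,
        )
    return FeatureSet(
        keypoints=np.array(pts), kinds=np.array(kinds, dtype=object),
        date_tag=image_meta.date_tag, border_flags=np.array(border, dtype=bool),
    )


# ---------------------------------------------------------------------------
# image-to-image alignment
# ---------------------------------------------------------------------------


def _similarity_from_pairs(src: np.ndarray, dst: np.ndarray) -> PlanarTransform | None:
    """Closed-form least-squares similarity mapping src -> dst (Umeyama)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    ps, pd = src - mu_s, dst - mu_d
    var_s = (ps**2).sum()
    if var_s <= 1e-30:
        return None
    # complex-number form of the 2D similarity fit
    zs = ps[:, 0] + 1j * ps[:, 1]
    zd = pd[:, 0] + 1j * pd[:, 1]
    a = np.vdot(zs, zd) / var_s
    scale = abs(a)
    if scale <= 1e-12:
        return None
    rot = math.atan2(a.imag, a.real)
    t = PlanarTransform(rotation=rot, scale=scale, translation=np.zeros(2))
    return PlanarTransform(rotation=rot, scale=scale,
                           translation=mu_d - t.apply(mu_s[None, :])[0])


def _mutual_nearest(a: np.ndarray, b: np.ndarray, max_dist: float):
    """Index pairs (i, j) that are mutual nearest neighbors within max_dist."""
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2), dtype=int)
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a)
    _, i_ba = ta.query(b)
    ii = np.arange(len(a))
    mutual = (i_ba[j_ab] == ii) & (d_ab <= max_dist)
    return np.column_stack([ii[mutual], j_ab[mutual]])


def align_images(reference: FeatureSet, moving: FeatureSet,
                 max_iter: int = 2000, inlier_tol: float = 0.03,
                 rng: np.random.Generator | int | None = 0,
                 max_rotation: float | None = None) -> PlanarTransform:
    """Robust similarity aligning ``moving`` keypoints onto ``reference``.

    Repeatedly samples a 2-point pair from each set (pairs with incompatible
    inter-point distances are skipped), fits the closed-form similarity,
    scores it by mutual-nearest inliers within ``inlier_tol``, keeps the
    best, then refits by least squares on the inliers.  ``max_rotation``
    (radians) discards candidate rotations beyond a known bound — useful on
    regular planting grids, whose near-180-degree symmetry can otherwise
    produce a spurious consensus.
    """
    ref = reference.keypoints
    mov = moving.keypoints
    if len(ref) < 2 or len(mov) < 2:
        raise InsufficientFeaturesError(
            f"need >= 2 keypoints per set, got {len(ref)} / {len(mov)}"
        )
    rng = np.random.default_rng(rng)

    def score(t: PlanarTransform):
        moved = t.apply(mov)
        pairs = _mutual_nearest(ref, moved, inlier_tol)
        if len(pairs) == 0:
            return 0, np.inf, pairs
        d = np.linalg.norm(ref[pairs[:, 0]] - moved[pairs[:, 1]], axis=1)
        return len(pairs), float(np.sqrt(np.mean(d**2))), pairs

    best = PlanarTransform.identity()
    best_n, best_rms, best_pairs = score(best)
    for _ in range(max_iter):
        i = rng.choice(len(mov), size=2, replace=False)
        j = rng.choice(len(ref), size=2, replace=False)
        dm = np.linalg.norm(mov[i[0]] - mov[i[1]])
        dr = np.linalg.norm(ref[j[0]] - ref[j[1]])
        if dm <= 1e-9 or not (0.8 <= dr / dm <= 1.25):  # scale gate with slack
            continue
        for jj in (j, j[::-1]):
            cand = _similarity_from_pairs(mov[i], ref[jj])
            if cand is None or not (0.85 <= cand.scale <= 1.18):
                continue
            if max_rotation is not None and abs(cand.rotation) > max_rotation:
                continue
            n, rms, pairs = score(cand)
            if n > best_n or (n == best_n and rms < best_rms):
                best, best_n, best_rms, best_pairs = cand, n, rms, pairs

    if best_n < 3:
        raise RegistrationFailureError(
            f"best consensus has only {best_n} inliers (< 3)"
        )
    refined = _similarity_from_pairs(mov[best_pairs[:, 1]], ref[best_pairs[:, 0]])
    if refined is not None:
        n, rms, pairs = score(refined)
        if n >= best_n:
            best, best_n, best_rms = refined, n, rms
    best.inlier_count = int(best_n)
    best.rms_residual = float(best_rms)
    return best


def chain_to_reference(transforms: list[PlanarTransform]) -> list[PlanarTransform]:
    """Compose date d -> d-1 transforms into date d -> date 1 transforms.

    ``transforms[d]`` maps date d+2's features onto date d+1's; the returned
    list has one entry per date, the first being identity.
    """
    out = [PlanarTransform.identity()]
    for t in transforms:
        out.append(out[-1].compose(t))
    return out
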