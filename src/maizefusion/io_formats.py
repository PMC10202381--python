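"""Point-cloud, image and trait-table containers plus file I/O.

All coordinates are meters in a right-handed frame with z up.  Point clouds
travel as PLY (ascii or binary little-endian) or whitespace/comma XYZ text;
integer label channels (``ground``, ``plant_id``, ``organ_id``) are stored as
int32 vertex properties so one file carries both geometry and ground truth.
Orthorectified images are plain PNG/TIFF rasters paired with a ground
sampling distance and a world origin: pixel (r, c) center maps to world
(origin_x + c*gsd, origin_y - r*gsd), i.e. row index grows with decreasing
world y.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

LABEL_CHANNELS = ("ground", "plant_id", "organ_id")

TRAIT_CSV_COLUMNS = ["date_tag", "plant_id", "organ_id", "trait_name", "value", "units"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """N x 3 float coordinates with optional RGB colors and label channels.

    Label channels are named int32 arrays of length N; ``ground`` is 0/1,
    ``plant_id`` and ``organ_id`` are -1 (unassigned) or non-negative.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    frame_id: str = "world"
    date_tag: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValidationError(
                    f"colors length {len(self.colors)} != points length {len(self.points)}"
                )
        clean = {}
        for name, arr in self.labels.items():
            arr = np.asarray(arr, dtype=np.int32).reshape(-1)
            if len(arr) != len(self.points):
                raise ValidationError(
                    f"label channel {name!r} length {len(arr)} != {len(self.points)}"
                )
            if name in ("plant_id", "organ_id") and arr.size and arr.min() < -1:
                raise ValidationError(f"{name} must be -1 or non-negative")
            if name == "ground" and arr.size and not np.isin(arr, (0, 1)).all():
                raise ValidationError("ground labels must be 0 or 1")
            clean[name] = arr
        self.labels = clean

    def __len__(self) -> int:
        return len(self.points)

    def select(self, idx) -> "PointCloud":
        """Sub-cloud at the given indices/boolean mask, labels preserved."""
        idx = np.asarray(idx)
        return PointCloud(
            points=self.points[idx],
            colors=None if self.colors is None else self.colors[idx],
            labels={k: v[idx] for k, v in self.labels.items()},
            frame_id=self.frame_id,
            date_tag=self.date_tag,
        )

    def with_points(self, points: np.ndarray, frame_id: str | None = None) -> "PointCloud":
        """Same attributes, new coordinates (e.g. after a transform)."""
        return replace(
            self,
            points=np.asarray(points, dtype=np.float64),
            frame_id=self.frame_id if frame_id is None else frame_id,
        )


@dataclass
class OrthoImage:
    """Top-view RGB raster with metric scale.

    ``gsd`` is meters per pixel; ``origin`` is the world (x, y) of the center
    of pixel (0, 0).  World y decreases with increasing row index.
    """

    pixels: np.ndarray
    gsd: float
    origin: tuple[float, float] = (0.0, 0.0)
    date_tag: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("pixels must be H x W x 3 uint8")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("image must have at least one pixel")
        if not (self.gsd > 0):
            raise ValidationError(f"gsd must be > 0, got {self.gsd}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self):
        return self.pixels.shape[:2]

    def pixel_to_world(self, rows, cols):
        """World (x, y) of pixel centers."""
        x = self.origin[0] + np.asarray(cols, dtype=float) * self.gsd
        y = self.origin[1] - np.asarray(rows, dtype=float) * self.gsd
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional (row, col) of world coordinates."""
        c = (np.asarray(x, dtype=float) - self.origin[0]) / self.gsd
        r = (self.origin[1] - np.asarray(y, dtype=float)) / self.gsd
        return r, c


@dataclass
class TraitTable:
    """Long-format per-plant / per-organ trait records.

    One row per (date_tag, plant_id, organ_id, trait_name); organ_id -1 means
    a whole-plant trait.
    """

    data: pd.DataFrame

    KEY = ["date_tag", "plant_id", "organ_id", "trait_name"]

    def __post_init__(self):
        df = pd.DataFrame(self.data, columns=TRAIT_CSV_COLUMNS)
        df = df.astype(
            {
                "date_tag": str,
                "plant_id": np.int64,
                "organ_id": np.int64,
                "trait_name": str,
                "value": np.float64,
                "units": str,
            }
        )
        if df.duplicated(self.KEY).any():
            dup = df[df.duplicated(self.KEY, keep=False)].iloc[0]
            raise ValidationError(
                f"duplicate trait key {tuple(dup[k] for k in self.KEY)}"
            )
        if not np.isfinite(df["value"].to_numpy()).all():
            raise ValidationError("trait values must be finite")
        self.data = df.sort_values(self.KEY, kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "TraitTable":
        return cls(pd.DataFrame(list(records), columns=TRAIT_CSV_COLUMNS))

    @classmethod
    def empty(cls) -> "TraitTable":
        return cls(pd.DataFrame(columns=TRAIT_CSV_COLUMNS))

    def __len__(self) -> int:
        return len(self.data)

    def filter(self, trait_name: str | None = None, date_tag: str | None = None) -> pd.DataFrame:
        df = self.data
        if trait_name is not None:
            df = df[df["trait_name"] == trait_name]
        if date_tag is not None:
            df = df[df["date_tag"] == date_tag]
        return df

    def concat(self, other: "TraitTable") -> "TraitTable":
        return TraitTable(pd.concat([self.data, other.data], ignore_index=True))


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_PLY_NAMES = {"i4": "int", "f8": "double", "u1": "uchar", "f4": "float"}


def _parse_ply_header(fh):
    """Returns (fmt, n_vertices, properties, header_bytes); fh positioned at data."""
    line = fh.readline()
    if line.strip() != b"ply":
        raise FormatError("not a PLY file: missing 'ply' magic at byte 0")
    fmt = None
    n_vertices = None
    properties = []  # (name, numpy dtype code) for the vertex element
    in_vertex = False
    nbytes = len(line)
    while True:
        raw = fh.readline()
        if not raw:
            raise FormatError(f"truncated PLY header at byte {nbytes}")
        nbytes += len(raw)
        tokens = raw.decode("ascii", errors="replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in (
                "ascii",
                "binary_little_endian",
            ):
                raise FormatError(f"unsupported PLY format line: {raw!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise FormatError(f"malformed element line at byte {nbytes}: {raw!r}")
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                try:
                    n_vertices = int(tokens[2])
                except ValueError:
                    raise FormatError(f"bad vertex count {tokens[2]!r}") from None
                if n_vertices < 0:
                    raise FormatError(f"negative vertex count {n_vertices}")
            elif tokens[2] != "0":
                raise FormatError(f"unsupported non-empty element {tokens[1]!r}")
        elif tokens[0] == "property" and in_vertex:
            if len(tokens) != 3 or tokens[1] == "list":
                raise FormatError(f"unsupported vertex property line: {raw!r}")
            if tokens[1] not in _PLY_DTYPES:
                raise FormatError(f"unknown PLY property type {tokens[1]!r}")
            properties.append((tokens[2], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt is None:
        raise FormatError("PLY header missing 'format' line")
    if n_vertices is None:
        raise FormatError("PLY header missing 'element vertex' line")
    for axis in "xyz":
        if axis not in [p[0] for p in properties]:
            raise FormatError(f"PLY vertex element missing {axis!r} property")
    return fmt, n_vertices, properties, nbytes


def _read_ply(path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, header_bytes = _parse_ply_header(fh)
        names = [p[0] for p in props]
        if fmt == "ascii":
            text = fh.read().decode("ascii", errors="replace")
            rows = [ln.split() for ln in text.splitlines() if ln.strip()]
            if len(rows) != n:
                raise FormatError(
                    f"vertex count mismatch: header says {n}, found {len(rows)} data rows"
                )
            if n == 0:
                data = {nm: np.empty(0, dtype=dt) for nm, dt in props}
            else:
                for i, row in enumerate(rows):
                    if len(row) != len(props):
                        raise FormatError(
                            f"row {i + 1} has {len(row)} fields, expected {len(props)}"
                        )
                try:
                    mat = np.array(rows, dtype=np.float64)
                except ValueError as exc:
                    raise FormatError(f"non-numeric PLY data: {exc}") from None
                data = {nm: mat[:, j].astype(dt) for j, (nm, dt) in enumerate(props)}
        else:
            dtype = np.dtype([(nm, "<" + dt) for nm, dt in props])
            buf = fh.read(dtype.itemsize * n)
            if len(buf) != dtype.itemsize * n:
                raise FormatError(
                    f"binary PLY truncated at byte {header_bytes + len(buf)}: "
                    f"expected {dtype.itemsize * n} data bytes"
                )
            rec = np.frombuffer(buf, dtype=dtype)
            data = {nm: rec[nm] for nm in names}

    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    colors = None
    if all(c in data for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data["red"], data["green"], data["blue"]]
        ).astype(np.uint8)
    labels = {
        name: data[name].astype(np.int32) for name in LABEL_CHANNELS if name in data
    }
    return PointCloud(points=points, colors=colors, labels=labels)


def _ply_header_lines(cloud: PointCloud, fmt: str) -> list[str]:
    lines = ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"]
    lines += [f"property double {axis}" for axis in "xyz"]
    if cloud.colors is not None:
        lines += [f"property uchar {c}" for c in ("red", "green", "blue")]
    for name in cloud.labels:
        lines.append(f"property int {name}")
    lines.append("end_header")
    return lines


def _write_ply(cloud: PointCloud, path, binary: bool):
    fmt = "binary_little_endian" if binary else "ascii"
    columns: list[tuple[np.ndarray, str]] = [
        (cloud.points[:, i], "<f8") for i in range(3)
    ]
    if cloud.colors is not None:
        columns += [(cloud.colors[:, i], "<u1") for i in range(3)]
    for arr in cloud.labels.values():
        columns.append((arr, "<i4"))

    with open(path, "wb") as fh:
        header = "\n".join(_ply_header_lines(cloud, fmt)) + "\n"
        fh.write(header.encode("ascii"))
        if binary:
            rec = np.empty(
                len(cloud), dtype=[(f"c{i}", dt) for i, (_, dt) in enumerate(columns)]
            )
            for i, (arr, _) in enumerate(columns):
                rec[f"c{i}"] = arr
            fh.write(rec.tobytes())
        else:
            out = io.StringIO()
            for row in range(len(cloud)):
                fields = []
                for arr, dt in columns:
                    v = arr[row]
                    fields.append(repr(float(v)) if dt == "<f8" else str(int(v)))
                out.write(" ".join(fields) + "\n")
            fh.write(out.getvalue().encode("ascii"))


# ---------------------------------------------------------------------------
# XYZ text
# ---------------------------------------------------------------------------


def _read_xyz(path, scale: float = 1.0) -> PointCloud:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, need >= 3"
                )
            try:
                rows.append([float(v) for v in parts[:6]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        return PointCloud(points=np.empty((0, 3)))
    width = min(len(r) for r in rows)
    mat = np.array([r[:width] for r in rows], dtype=np.float64)
    points = mat[:, :3] * scale
    colors = None
    if width >= 6:
        colors = np.clip(mat[:, 3:6], 0, 255).astype(np.uint8)
    return PointCloud(points=points, colors=colors)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read_point_cloud(path, format_hint: str = "auto", scale: float = 1.0) -> PointCloud:
    """Read a PLY or XYZ/CSV text point cloud.

    ``scale`` multiplies XYZ-text coordinates (e.g. 0.001 for millimeter
    files); PLY files are assumed to be in meters already.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format_hint == "auto":
        with open(path, "rb") as fh:
            magic = fh.read(3)
        format_hint = "ply" if magic == b"ply" else "xyz"
    if format_hint == "ply":
        return _read_ply(path)
    if format_hint == "xyz":
        return _read_xyz(path, scale=scale)
    raise ValidationError(f"unknown format hint {format_hint!r}")


def write_point_cloud(cloud: PointCloud, path, format: str = "ply_binary"):
    """Write a cloud as ``ply_ascii``, ``ply_binary`` or ``xyz`` text."""
    if format == "ply_ascii":
        _write_ply(cloud, path, binary=False)
    elif format == "ply_binary":
        _write_ply(cloud, path, binary=True)
    elif format == "xyz":
        with open(path, "w", encoding="utf-8") as fh:
            for i in range(len(cloud)):
                fields = [repr(float(v)) for v in cloud.points[i]]
                if cloud.colors is not None:
                    fields += [str(int(v)) for v in cloud.colors[i]]
                fh.write(" ".join(fields) + "\n")
    else:
        raise ValidationError(f"unknown point cloud format {format!r}")
    return path


def read_ortho_image(path, gsd: float, origin=(0.0, 0.0), date_tag: str = "") -> OrthoImage:
    """Read a PNG/TIFF as an orthorectified RGB image.

    Grayscale is promoted by channel replication; 16-bit data is rescaled to
    uint8 by max-scaling (pixel * 255 / max).
    """
    if not (gsd > 0):
        raise ValidationError(f"gsd must be > 0, got {gsd}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot decode image {path}: {exc}") from None
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        peak = float(arr.max()) if arr.size else 1.0
        arr = (arr.astype(np.float64) * (255.0 / max(peak, 1.0))).round()
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return OrthoImage(pixels=arr, gsd=float(gsd), origin=origin, date_tag=date_tag)


def write_ortho_image(image: OrthoImage, path):
    iio.imwrite(path, image.pixels)
    return path


def write_trait_table(table: TraitTable, path):
    """Write a trait table as UTF-8 CSV sorted by key."""
    table.data.to_csv(path, index=False, encoding="utf-8")
    return path


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRAIT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trait CSV {path} missing columns {missing}")
    return TraitTable(df)


def read_label_sidecar(path, cloud: PointCloud) -> PointCloud:
    """Attach label channels from a sidecar CSV (columns ground/plant_id/organ_id)."""
    df = pd.read_csv(path)
    if len(df) != len(cloud):
        raise ValidationError(
            f"sidecar has {len(df)} rows but cloud has {len(cloud)} points"
        )
    labels = dict(cloud.labels)
    for name in LABEL_CHANNELS:
        if name in df.columns:
            labels[name] = df[name].to_numpy(dtype=np.int32)
    return replace(cloud, labels=labels)
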