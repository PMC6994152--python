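"""Reading and validating organoid boundary traces.

Boundaries are ordered closed polygons of segmentation vertices in pixel
units, one per organoid, grouped by tumor.  Two on-disk forms are supported:
plain two-column CSV/TSV (x, y; full float precision) and the ImageJ ``.roi``
single-ROI binary for polygon/freehand traces (integer coordinates, the form
produced by manual tracing in ImageJ).

Conventions: x is the column index and y the row index, 0-based, origin at
the image top-left.  Boundaries are stored *open* — the closing edge from the
last vertex back to the first is implicit and all geometry uses periodic
indexing.  A duplicated terminal vertex equal to the first is dropped on read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from invaspect.exceptions import DegenerateBoundaryError, UnsupportedFormatError

__all__ = [
    "RawBoundary",
    "ImageMeta",
    "Cohort",
    "read_boundary",
    "write_boundary_csv",
    "write_imagej_roi",
    "load_cohort",
]

# ImageJ resolution used for the original acquisitions; callers may override.
DEFAULT_UM_PER_PX = 0.51190476

# ImageJ ROI type codes (RoiDecoder): only closed traced outlines are polygons.
_ROI_POLYGON = 0
_ROI_FREEHAND = 7
_ROI_TRACED = 8
_CLOSED_ROI_TYPES = {_ROI_POLYGON, _ROI_FREEHAND, _ROI_TRACED}


@dataclass(frozen=True)
class ImageMeta:
    """Image frame geometry: pixel dimensions and physical resolution."""

    height_px: int
    width_px: int
    um_per_px: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0 or self.um_per_px <= 0:
            raise ValueError("image dimensions and resolution must be positive")

    @property
    def pixel_count(self) -> int:
        return self.height_px * self.width_px


@dataclass(frozen=True)
class RawBoundary:
    """An ordered closed polygon of trace vertices in pixel units.

    ``vertices`` is a (V, 2) float array of (x, y) pairs in trace order.
    Closure is implicit: vertex V-1 connects back to vertex 0.
    """

    vertices: np.ndarray
    tumor_id: str = ""
    organoid_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (V, 2) array of (x, y) pairs")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        # drop a duplicated terminal vertex equal to the first
        if len(v) > 1 and np.array_equal(v[0], v[-1]):
            v = v[:-1]
        # collapse identical consecutive vertices (periodically closed)
        if len(v) > 1:
            keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
            v = v[keep]
        if len(v) < 3:
            raise DegenerateBoundaryError(
                f"boundary {self.tumor_id}/{self.organoid_id}: "
                f"fewer than 3 distinct vertices"
            )
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def translated(self, dx: float, dy: float) -> "RawBoundary":
        return RawBoundary(self.vertices + [dx, dy], self.tumor_id, self.organoid_id)


def read_boundary(
    path: str | Path,
    format: str | None = None,
    tumor_id: str = "",
    organoid_id: str = "",
) -> RawBoundary:
    """Read one boundary trace from ``path``.

    ``format`` is ``"csv"`` or ``"imagej_roi"``; when omitted it is inferred
    from the file extension (``.roi`` -> ImageJ, anything else -> CSV/TSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "imagej_roi" if path.suffix.lower() == ".roi" else "csv"
    if format == "csv":
        vertices = _read_csv_vertices(path)
    elif format == "imagej_roi":
        vertices = _read_imagej_roi(path)
    else:
        raise ValueError(f"unknown boundary format {format!r}")
    return RawBoundary(vertices, tumor_id=tumor_id, organoid_id=organoid_id)


def _read_csv_vertices(path: Path) -> np.ndarray:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    # tolerate an optional single header row
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    header = 0 if any(c.isalpha() for c in first) else None
    df = pd.read_csv(path, sep=sep, header=header, comment="#",
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise UnsupportedFormatError(f"{path}: expected two numeric columns (x, y)")
    return df.iloc[:, :2].to_numpy(dtype=float)


def _read_imagej_roi(path: Path) -> np.ndarray:
    """Decode the polygon/freehand subset of the ImageJ .roi binary format.

    Layout (big-endian): magic "Iout", version int16, roi type byte, bounds
    (top, left, bottom, right) int16 at offsets 8..15, n int16 at 16, and at
    offset 64 the x then y coordinate arrays as int16 relative to (left, top).
    """
    data = path.read_bytes()
    if len(data) < 64 or data[:4] != b"Iout":
        raise UnsupportedFormatError(f"{path}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in _CLOSED_ROI_TYPES:
        raise UnsupportedFormatError(
            f"{path}: ROI type {roi_type} is not a closed polygon/freehand trace"
        )
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    (n,) = struct.unpack(">h", data[16:18])
    if n < 3:
        raise DegenerateBoundaryError(f"{path}: ROI has fewer than 3 vertices")
    coords = np.frombuffer(data, dtype=">i2", count=2 * n, offset=64).astype(float)
    x = coords[:n] + left
    y = coords[n:] + top
    return np.column_stack([x, y])


def write_boundary_csv(boundary: RawBoundary, path: str | Path) -> None:
    """Write vertices as an ``x,y`` CSV with a header, losslessly round-trippable."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x,y\n")
        for x, y in boundary.vertices:
            # repr is the shortest decimal string that round-trips a float64
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def write_imagej_roi(vertices: np.ndarray, path: str | Path, roi_type: int = _ROI_POLYGON) -> None:
    """Write integer vertices as a minimal ImageJ polygon ``.roi`` file."""
    v = np.asarray(vertices)
    vi = np.round(v).astype(int)
    if not np.allclose(v, vi):
        raise ValueError("ImageJ ROI files store integer coordinates")
    left, top = vi[:, 0].min(), vi[:, 1].min()
    right, bottom = vi[:, 0].max(), vi[:, 1].max()
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, len(vi))
    body = np.concatenate([vi[:, 0] - left, vi[:, 1] - top]).astype(">i2").tobytes()
    Path(path).write_bytes(bytes(header) + body)


@dataclass
class Cohort:
    """Boundaries for a cohort of organoids, grouped by tumor."""

    boundaries: list[RawBoundary] = field(default_factory=list)
    image_paths: dict[tuple[str, str], Path] = field(default_factory=dict)

    @property
    def n_organoids(self) -> int:
        return len(self.boundaries)

    @property
    def tumor_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.boundaries:
            seen.setdefault(b.tumor_id)
        return list(seen)

    @property
    def n_tumors(self) -> int:
        return len(self.tumor_ids)

    def organoids_per_tumor(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.boundaries:
            counts[b.tumor_id] = counts.get(b.tumor_id, 0) + 1
        return counts

    def __iter__(self):
        return iter(self.boundaries)


def load_cohort(manifest: str | Path | pd.DataFrame) -> Cohort:
    """Load a cohort from a manifest of (tumor_id, organoid_id, boundary_path[, image_path]).

    A path argument is read as a TSV with a header; paths in the manifest are
    resolved relative to the manifest's directory.
    """
    base = Path(".")
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        base = mpath.parent
        manifest = pd.read_csv(mpath, sep="\t", dtype=str)
    required = {"tumor_id", "organoid_id", "boundary_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    keys = list(zip(manifest["tumor_id"], manifest["organoid_id"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (tumor_id, organoid_id) keys in manifest: {dupes}")
    cohort = Cohort()
    for idx, row in manifest.iterrows():
        bpath = base / row["boundary_path"]
        if not bpath.exists():
            raise FileNotFoundError(
                f"manifest row {idx} ({row['tumor_id']}/{row['organoid_id']}): "
                f"missing boundary file {bpath}"
            )
        cohort.boundaries.append(
            read_boundary(bpath, tumor_id=row["tumor_id"], organoid_id=row["organoid_id"])
        )
        ipath = row.get("image_path") if hasattr(row, "get") else None
        if isinstance(ipath, str) and ipath:
            cohort.image_paths[(row["tumor_id"], row["organoid_id"])] = base / ipath
    return cohort
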