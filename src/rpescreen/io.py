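"""Image, ROI and manifest input/output plus polygon rasterization.

Coordinate convention used throughout the package
-------------------------------------------------
Polygon vertices are ``(row, col)`` pairs of floats, 0-based, with
pixel-center semantics: integer coordinates name the *center* of a pixel
and the row index increases downward (standard image convention).
Dorsal is the row-decreasing direction ("up" in the image).

ImageJ ``.roi`` files store 0-based integer x (column) / y (row)
coordinates; this module reads polygon and freehand subtypes and writes
polygon ROIs, rounding vertices to the nearest integer pixel (use the
JSON writer to preserve sub-pixel vertices exactly).
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "RoiMask",
    "read_image",
    "write_image",
    "read_roi",
    "write_roi_imagej",
    "write_roi_json",
    "rasterize",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ["image", "roi", "group", "larva_id", "ablated"]

# ImageJ .roi header constants (big-endian).  Only the polygon-family
# subtypes carry a plain vertex list.
_ROI_MAGIC = b"Iout"
_ROI_VERSION = 227
_ROI_TYPE_POLYGON = 0
_ROI_TYPE_FREEHAND = 7
_ROI_HEADER_SIZE = 64


@dataclass(frozen=True)
class RoiMask:
    """Binary ROI raster aligned to its image."""

    mask: np.ndarray  # bool, same shape as the image
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("RoiMask must cover at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of pixels inside the ROI."""
        return np.nonzero(self.mask)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF as an 8-bit raster.

    16-bit input is linearly rescaled to 0..255 with a warning; RGB or
    multi-channel input is rejected (convert to single-channel grayscale
    upstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # corrupt / not a TIFF
        raise ValueError(f"could not read TIFF image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale image, got shape "
            f"{arr.shape}; convert RGB/stacks to 8-bit grayscale first"
        )
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        warnings.warn(
            f"{path}: 16-bit image linearly rescaled to 8-bit", stacklevel=2
        )
        return np.rint(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8/uint16")


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale TIFF."""
    image = np.asarray(image)
    if image.ndim != 2 or image.dtype != np.uint8:
        raise ValueError("write_image expects a 2-D uint8 array")
    tifffile.imwrite(str(path), image)


# ---------------------------------------------------------------------------
# ROI polygons


def _vertices_array(vertices: Sequence[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(vertices, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("a polygon needs >= 3 (row, col) vertices")
    return arr


def read_roi(path: str | Path) -> np.ndarray:
    """Read an ROI polygon from an ImageJ ``.roi`` or a JSON vertex file.

    Returns an ``(n, 2)`` float array of 0-based ``(row, col)`` vertices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    if path.suffix.lower() == ".roi":
        return _read_imagej_roi(path.read_bytes(), name=str(path))
    data = json.loads(path.read_text())
    if not isinstance(data, dict) or "vertices" not in data:
        raise ValueError(f"{path}: JSON ROI must be an object with a 'vertices' key")
    return _vertices_array(data["vertices"])


def _read_imagej_roi(buf: bytes, name: str = "<bytes>") -> np.ndarray:
    if len(buf) < _ROI_HEADER_SIZE or buf[:4] != _ROI_MAGIC:
        raise ValueError(f"{name}: not an ImageJ .roi file")
    roi_type = buf[6]
    if roi_type not in (_ROI_TYPE_POLYGON, _ROI_TYPE_FREEHAND):
        raise ValueError(
            f"{name}: unsupported ROI type {roi_type}; only polygon/freehand "
            "ROIs carry a vertex outline"
        )
    top, left, _bottom, _right, n = struct.unpack(">hhhhh", buf[8:18])
    if n < 3:
        raise ValueError(f"{name}: polygon ROI has {n} < 3 vertices")
    end = _ROI_HEADER_SIZE + 4 * n
    if len(buf) < end:
        raise ValueError(f"{name}: truncated .roi coordinate block")
    xs = np.frombuffer(buf, dtype=">i2", count=n, offset=_ROI_HEADER_SIZE)
    ys = np.frombuffer(buf, dtype=">i2", count=n, offset=_ROI_HEADER_SIZE + 2 * n)
    rows = ys.astype(np.float64) + top
    cols = xs.astype(np.float64) + left
    return np.column_stack([rows, cols])


def write_roi_imagej(path: str | Path, vertices: Sequence[Sequence[float]]) -> None:
    """Write a polygon ROI as an ImageJ ``.roi`` (vertices rounded to int)."""
    arr = np.rint(_vertices_array(vertices)).astype(np.int64)
    rows, cols = arr[:, 0], arr[:, 1]
    top, left = int(rows.min()), int(cols.min())
    bottom, right = int(rows.max()), int(cols.max())
    n = len(arr)
    header = bytearray(_ROI_HEADER_SIZE)
    header[:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, _ROI_VERSION)
    header[6] = _ROI_TYPE_POLYGON
    struct.pack_into(">hhhhh", header, 8, top, left, bottom, right, n)
    xs = (cols - left).astype(">i2").tobytes()
    ys = (rows - top).astype(">i2").tobytes()
    Path(path).write_bytes(bytes(header) + xs + ys)


def write_roi_json(path: str | Path, vertices: Sequence[Sequence[float]]) -> None:
    """Write an ROI polygon as JSON, preserving sub-pixel vertices."""
    arr = _vertices_array(vertices)
    payload = {
        "vertices": arr.tolist(),
        "coordinate_order": "row_col",
        "origin": "zero_based_pixel_center",
    }
    Path(path).write_text(json.dumps(payload))


def rasterize(vertices: Sequence[Sequence[float]], image_shape: tuple[int, int]) -> RoiMask:
    """Rasterize a simple polygon to a pixel mask.

    A pixel belongs to the mask iff its center lies inside the polygon;
    centers exactly on the polygon boundary are included (closed-polygon
    rule).  Deterministic by construction.
    """
    arr = _vertices_array(vertices)
    poly = _ShapelyPolygon(np.column_stack([arr[:, 1], arr[:, 0]]))  # (x=col, y=row)
    if not poly.is_valid or poly.area == 0.0:
        raise ValueError("degenerate (zero-area or self-intersecting) polygon")
    h, w = image_shape
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = int(np.floor(minx)), int(np.ceil(maxx))
    r0, r1 = int(np.floor(miny)), int(np.ceil(maxy))
    if c1 < 0 or r1 < 0 or c0 > w - 1 or r0 > h - 1:
        raise ValueError("polygon lies entirely outside the image frame")
    c0, r0 = max(c0, 0), max(r0, 0)
    c1, r1 = min(c1, w - 1), min(r1, h - 1)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel()).reshape(cc.shape)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    count = int(mask.sum())
    if count == 0:
        raise ValueError("polygon covers no pixel centers inside the frame")
    return RoiMask(mask=mask, pixel_count=count)


# ---------------------------------------------------------------------------
# Cohort manifest


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load a cohort manifest CSV (image, roi, group, larva_id, ablated).

    Relative image/roi paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"group": str, "larva_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["larva_id"].duplicated().any():
        dupes = df.loc[df["larva_id"].duplicated(), "larva_id"].tolist()
        raise ValueError(f"{path}: duplicate larva_id values {dupes}")
    if (df["group"].isna() | (df["group"].str.len() == 0)).any():
        raise ValueError(f"{path}: empty group labels")
    base = path.parent
    for col in ("image", "roi"):
        df[col] = df[col].map(lambda p: str((base / p) if not Path(p).is_absolute() else Path(p)))
    if check_files:
        for col in ("image", "roi"):
            for p in df[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{path}: referenced file missing: {p}")
    df["ablated"] = df["ablated"].astype(bool)
    return df[MANIFEST_COLUMNS]


def write_manifest(path: str | Path, rows: pd.DataFrame) -> None:
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)
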