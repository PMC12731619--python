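"""Reading and writing of images, probability masks, ROIs, trajectories and tables.

All in-memory grids are 0-based, row-major numpy arrays with the origin at the
top-left. Polygon vertices are ``(x=column, y=row)`` pairs in the ImageJ
convention; the center of pixel ``(row, col)`` sits at ``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

import csv
import dataclasses
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityImage",
    "ProbabilityMask",
    "RoiSpec",
    "QuantRecord",
    "read_raster",
    "roi_to_mask",
    "read_roi",
    "write_roi_txt",
    "write_imagej_roi",
    "read_trajectory_table",
    "write_table",
    "read_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensityImage:
    """A single-channel 2D image of nonnegative intensities."""

    pixels: np.ndarray
    pixel_size_um: float | None = None
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("intensity image must be a non-empty 2D grid")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ProbabilityMask:
    """Per-pixel probability that the pixel belongs to the signal of interest.

    ``source_scale`` records the on-disk encoding the values were normalized
    from: ``"unit"`` (already in [0,1]), ``"eight_bit"`` or ``"sixteen_bit"``.
    """

    probs: np.ndarray
    channel_name: str = ""
    source_scale: str = "unit"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.size == 0:
            raise ValueError("probability mask must be a non-empty 2D grid")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape  # type: ignore[return-value]


@dataclass
class RoiSpec:
    """A region of interest: either a polygon outline or a boolean mask."""

    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None
    name: str = "roi"

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("provide exactly one of polygon or mask")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=np.float64)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
                raise ValueError("polygon must be an (n, 2) array of (x, y)")
            if len(self.polygon) < 3:
                raise ValueError("polygon needs at least 3 vertices")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("mask must be 2D")
            if not self.mask.any():
                raise ValueError("ROI mask is empty")


@dataclass
class QuantRecord:
    """One row of the quantification results table."""

    image_id: str
    signal_name: str
    roi_area_px: int
    signal_area_px: int
    area_percent: float
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.roi_area_px <= 0:
            raise ValueError("roi_area_px must be positive")
        expect = 100.0 * self.signal_area_px / self.roi_area_px
        if abs(self.area_percent - expect) > 1e-9:
            raise ValueError("area_percent inconsistent with areas")


# ---------------------------------------------------------------------------
# raster reading
# ---------------------------------------------------------------------------

def read_raster(
    path: str | Path,
    expected: Literal["intensity", "probability"],
    channel: int | None = None,
    channel_name: str = "",
) -> IntensityImage | ProbabilityMask:
    """Read a TIFF or PNG raster as an intensity image or a probability mask.

    Probability data stored as unsigned integers is rescaled by the dtype
    maximum (8-bit by 255, 16-bit by 65535); float data must already be in
    [0, 1].  Multi-page/multi-channel files require an explicit ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3:
        # channels may come first (pages) or last (interleaved)
        axis = 0 if data.shape[0] <= 8 and data.shape[0] < data.shape[2] else 2
        if channel is None:
            if data.shape[axis] == 1:
                channel = 0
            else:
                raise ValueError(
                    f"{path} has {data.shape[axis]} channels; pass channel="
                )
        data = np.take(data, channel, axis=axis)
    if data.ndim != 2 or data.size == 0:
        raise ValueError(f"{path}: expected a non-empty 2D image")

    if expected == "intensity":
        return IntensityImage(data.astype(np.float64), channel_name=channel_name)
    if expected == "probability":
        if data.dtype == np.uint8:
            probs, scale = data / 255.0, "eight_bit"
        elif data.dtype == np.uint16:
            probs, scale = data / 65535.0, "sixteen_bit"
        else:
            probs, scale = data.astype(np.float64), "unit"
            if probs.min() < 0 or probs.max() > 1:
                raise ValueError(
                    f"{path}: float probability values outside [0, 1]"
                )
        return ProbabilityMask(probs, channel_name=channel_name, source_scale=scale)
    raise ValueError(f"unknown expected kind: {expected!r}")


# ---------------------------------------------------------------------------
# ROI handling
# ---------------------------------------------------------------------------

def _polygon_contains(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd containment test, vectorized over ``points`` (n, 2) (x, y).

    Points exactly on a polygon edge count as inside.
    """
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment check: zero cross product and within the bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (np.minimum(x1, x2) - 1e-12 <= px)
            & (px <= np.maximum(x1, x2) + 1e-12)
            & (np.minimum(y1, y2) - 1e-12 <= py)
            & (py <= np.maximum(y1, y2) + 1e-12)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
        # half-open crossing rule avoids double-counting vertices
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
        inside ^= crosses & (px < x_at)
    return inside | on_edge


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def roi_to_mask(roi: RoiSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ROI to a boolean mask of ``shape`` (rows, cols).

    A pixel is included iff its center (col+0.5, row+0.5) lies inside the
    polygon under the even-odd rule; centers exactly on an edge are included.
    Mask-backed ROIs are returned unchanged (after a shape check).
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive in both dimensions")
    if roi.mask is not None:
        if roi.mask.shape != (rows, cols):
            raise ValueError(
                f"ROI mask shape {roi.mask.shape} != target shape {shape}"
            )
        return roi.mask.copy()
    verts = roi.polygon
    assert verts is not None
    if _polygon_area(verts) == 0.0:
        raise ValueError("degenerate polygon (zero area)")
    rr, cc = np.mgrid[0:rows, 0:cols]
    centers = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    mask = _polygon_contains(centers, verts).reshape(rows, cols)
    if not mask.any():
        raise ValueError("polygon covers no pixel centers inside the grid")
    return mask


# --- ImageJ .roi binary format (polygon/freehand subset) -------------------

_IJ_POLYGON, _IJ_FREEHAND = 0, 7


def read_roi(path: str | Path) -> RoiSpec:
    """Read an ROI from an ImageJ ``.roi`` file or a plain-text polygon file.

    Text files carry one ``x,y`` vertex per line.  Only polygon-type ImageJ
    ROIs are supported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".roi":
        blob = path.read_bytes()
        if blob[:4] != b"Iout":
            raise ValueError(f"{path} is not an ImageJ ROI file")
        roi_type = blob[6]
        if roi_type not in (_IJ_POLYGON, _IJ_FREEHAND):
            raise ValueError(f"unsupported ImageJ ROI type {roi_type}")
        top, left, _bottom, _right, n = struct.unpack(">5h", blob[8:18])
        xs = np.frombuffer(blob, dtype=">i2", count=n, offset=64).astype(float)
        ys = np.frombuffer(blob, dtype=">i2", count=n, offset=64 + 2 * n).astype(float)
        verts = np.column_stack([xs + left, ys + top])
        return RoiSpec(polygon=verts, name=path.stem)
    verts_list = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y = line.split(",")
        verts_list.append((float(x), float(y)))
    return RoiSpec(polygon=np.asarray(verts_list), name=path.stem)


def write_roi_txt(roi: RoiSpec, path: str | Path) -> None:
    """Write a polygon ROI as plain text, one ``x,y`` vertex per line."""
    if roi.polygon is None:
        raise ValueError("only polygon ROIs can be written as text")
    lines = [f"{x:g},{y:g}" for x, y in roi.polygon]
    Path(path).write_text("\n".join(lines) + "\n")


def write_imagej_roi(roi: RoiSpec, path: str | Path) -> None:
    """Write a polygon ROI in the binary ImageJ ``.roi`` format."""
    if roi.polygon is None:
        raise ValueError("only polygon ROIs can be written as .roi")
    verts = np.round(roi.polygon).astype(int)
    xs, ys = verts[:, 0], verts[:, 1]
    left, top = int(xs.min()), int(ys.min())
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = _IJ_POLYGON
    struct.pack_into(
        ">5h", header, 8, top, left, int(ys.max()), int(xs.max()), len(verts)
    )
    body = (xs - left).astype(">i2").tobytes() + (ys - top).astype(">i2").tobytes()
    Path(path).write_bytes(bytes(header) + body)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_trajectory_table(path: str | Path) -> pd.DataFrame:
    """Read a trajectory file with required columns ``t, x, y`` (header row)."""
    df = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {sorted(missing)}")
    return df[["t", "x", "y"] + [c for c in df.columns if c not in ("t", "x", "y")]]


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    if len(records) and dataclasses.is_dataclass(records[0]):
        cols = [f.name for f in dataclasses.fields(records[0])]
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in records], columns=cols
        )
    return pd.DataFrame(list(records))


def write_table(records: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write records as CSV with a fixed column order and sorted rows.

    Rows are sorted by ``(image_id, signal_name)`` when those columns exist.
    Floats are written with ``repr`` so re-reading reproduces them exactly;
    writing the same records twice yields byte-identical files.
    """
    df = records.copy() if isinstance(records, pd.DataFrame) else _records_to_frame(records)
    sort_cols = [c for c in ("image_id", "signal_name", "fly_id") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(df.columns.tolist())
        for row in df.itertuples(index=False):
            writer.writerow([repr(v) if isinstance(v, float) else v for v in row])


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`."""
    return pd.read_csv(path)
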