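"""Calibrated image-stack, contour and metric-table I/O.

The raw input to every imaging stage is a :class:`FrameStack`: a grayscale
time-lapse of the beating ventricle together with its frame rate (frames per
second) and spatial calibration (micrometres per pixel).  Stacks are read from
multi-page TIFF files or from directories of lexically ordered single-page
images.  Manually traced lumen outlines travel as a :class:`ContourSet`
(per-frame closed polygons in pixel coordinates), and computed metrics are
written as flat CSV/JSON tables.

Coordinate convention (used package-wide): pixel coordinates are 0-based with
``x`` along columns and ``y`` along rows; pixel centers sit at integer
coordinates; areas in px^2 convert to um^2 through ``pixel_size**2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .errors import FormatError, InputError

__all__ = [
    "FrameStack",
    "ContourSet",
    "read_stack",
    "write_stack",
    "read_contours",
    "polygon_area",
    "write_metrics",
    "read_metrics",
]

#: image-sequence extensions accepted when reading a directory
_SEQ_EXTENSIONS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass
class FrameStack:
    """A calibrated grayscale video: frames x rows x cols plus timing.

    Parameters
    ----------
    frames
        3-D intensity array ``(time, rows, cols)``.  Integer dtypes are kept
        as acquired (8/16-bit) so that writing back to TIFF is lossless;
        downstream analysis promotes to float.
    fps
        Acquisition frame rate in frames per second (> 0).
    pixel_size
        Spatial calibration in micrometres per pixel (> 0).
    times
        Per-frame timestamps in milliseconds.  Derived as ``index / fps``
        (in ms) when not supplied.
    """

    frames: np.ndarray
    fps: float
    pixel_size: float
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be 3-D (time, rows, cols); got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise FormatError("a stack needs at least 2 frames")
        if not self.fps > 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if not self.pixel_size > 0:
            raise FormatError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float) * (1000.0 / self.fps)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise FormatError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise FormatError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def duration_ms(self) -> float:
        """Total recorded duration, counting one inter-frame interval per frame."""
        return self.n_frames * 1000.0 / self.fps

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class ContourSet:
    """Per-frame closed polygons (lumen outlines) in pixel coordinates.

    ``polygons`` maps frame index to an ``(n, 2)`` float array of ``(x, y)``
    vertices; polygons are closed implicitly (last vertex joins the first).
    """

    polygons: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for frame, poly in self.polygons.items():
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise FormatError(
                    f"frame {frame}: polygon needs >=3 (x, y) vertices"
                )
            if abs(polygon_area(poly)) <= 0:
                raise FormatError(f"frame {frame}: polygon has zero area")
            if _self_intersects(poly):
                raise FormatError(f"frame {frame}: polygon is self-intersecting")
            self.polygons[frame] = poly

    @property
    def frame_indices(self) -> list[int]:
        return sorted(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.polygons[frame]


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive = CCW in x/y)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_cross(p1, p2, p3, p4) -> bool:
    """True if open segments p1-p2 and p3-p4 properly intersect."""

    def orient(a, b, c):
        u, v = b - a, c - a
        return np.sign(u[0] * v[1] - u[1] * v[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return d1 != d2 and d3 != d4 and 0 not in (d1, d2, d3, d4)


def _self_intersects(poly: np.ndarray) -> bool:
    n = poly.shape[0]
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # shared vertex with closing edge
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


def read_stack(path: str | Path, fps: float, pixel_size: float) -> FrameStack:
    """Read a multi-page TIFF or an image-sequence directory as a FrameStack.

    Directory frames are taken in lexical filename order.  8/16-bit images
    keep their native dtype; multichannel pages are rejected.

    Raises
    ------
    InputError
        If ``path`` does not exist.
    FormatError
        On inconsistent frame shapes, non-grayscale data or < 2 frames.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SEQ_EXTENSIONS
        )
        if len(files) < 2:
            raise FormatError(
                f"{path}: need >=2 image files, found {len(files)}"
            )
        frames = []
        for f in files:
            img = np.asarray(iio.imread(f))
            if img.ndim != 2:
                raise FormatError(f"{f}: expected 2-D grayscale, got shape {img.shape}")
            frames.append(img)
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise FormatError(f"{path}: inconsistent frame shapes {sorted(shapes)}")
        data = np.stack(frames)
    else:
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            raise FormatError(f"{path}: single-page TIFF; a stack needs >=2 frames")
        if data.ndim != 3:
            raise FormatError(
                f"{path}: expected grayscale pages, got array shape {data.shape}"
            )

    return FrameStack(frames=data, fps=fps, pixel_size=pixel_size)


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a FrameStack as a multi-page grayscale TIFF (lossless)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    return path


def read_contours(path: str | Path) -> ContourSet:
    """Read per-frame lumen outlines from a ``frame,x,y`` CSV.

    Vertices are grouped by frame index in file order; each frame's polygon
    is closed implicitly.  Fewer than 3 vertices for a frame, or non-numeric
    cells, raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty contour file") from exc
    required = {"frame", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: contour CSV needs columns frame,x,y; got {list(df.columns)}"
        )
    if df.empty:
        raise FormatError(f"{path}: contour CSV has no vertices")
    for col in ("frame", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            raise FormatError(f"{path}: non-numeric value in column '{col}'")
        df[col] = coerced

    polygons: dict[int, np.ndarray] = {}
    for frame, grp in df.groupby("frame", sort=True):
        verts = grp[["x", "y"]].to_numpy(dtype=float)
        if verts.shape[0] < 3:
            raise FormatError(
                f"{path}: frame {int(frame)} has {verts.shape[0]} vertices (<3)"
            )
        polygons[int(frame)] = verts
    return ContourSet(polygons=polygons)


def _as_records(records) -> list[dict]:
    if isinstance(records, pd.DataFrame):
        recs = records.to_dict(orient="records")
    elif isinstance(records, Mapping):
        recs = [dict(records)]
    else:
        recs = [dict(r) for r in records]
    if not recs:
        raise FormatError("records must be non-empty")
    keys = set(recs[0])
    if any(set(r) != keys for r in recs):
        raise FormatError("records must have homogeneous keys")
    return recs


def write_metrics(records, path: str | Path, format: str = "csv") -> Path:
    """Write named metrics as CSV or JSON.

    Accepts a single mapping, an iterable of mappings, or a DataFrame.
    Column order is the key order of the first record (deterministic);
    floats are written with 12 significant digits so a write/read round-trip
    is lossless at that precision.
    """
    recs = _as_records(records)
    path = Path(path)
    columns = list(recs[0].keys())
    if format == "csv":
        df = pd.DataFrame(recs, columns=columns)
        try:
            df.to_csv(path, index=False, float_format="%.12g")
        except OSError as exc:
            raise InputError(f"cannot write {path}: {exc}") from exc
    elif format == "json":
        try:
            with open(path, "w") as fh:
                json.dump(recs, fh, indent=2, default=float)
        except OSError as exc:
            raise InputError(f"cannot write {path}: {exc}") from exc
    else:
        raise FormatError(f"unknown metrics format: {format!r}")
    return path


def read_metrics(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read back a metrics table written by :func:`write_metrics`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise FormatError(f"unknown metrics format: {format!r}")
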