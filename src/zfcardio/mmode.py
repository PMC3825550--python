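"""M-mode (pseudo-linescan) cardiac analysis.

An M-mode image is built by sampling, in every video frame, the intensity
profile along one fixed single-pixel-wide line through the ventricular
center of mass; stacking one profile per frame gives a position x time
image in which wall motion appears as bright/dark traces.  From the long-
and short-axis M-modes this module measures:

* ``VDs`` / ``VDd`` - end-systolic / end-diastolic internal dimensions,
  taken at the maximal inward / outward wall excursions and averaged over
  five cycles by default;
* ``EDV`` / ``ESV`` / ``SV`` - ventricular volumes from the prolate-spheroid
  model, and ``EF`` = SV/EDV, ``%FS`` = 100(short VDd - short VDs)/short VDd;
* ``mVWVs`` / ``mVWVd`` - mean ventricular wall velocities during systole /
  diastole, from slopes between consecutive extrema of the ventral wall
  trace (the classic 11-point scheme: 6 inward + 5 outward points giving
  five systolic and five diastolic slopes);
* heart rate, by counting beats over a 15 s window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import AnalysisError
from .io import FrameStack
from .segmentation import fit_stack
from .volume import prolate_volume_pl

__all__ = [
    "MModeImage",
    "WallTrace",
    "ExtremePoint",
    "MModeMetrics",
    "HeartRate",
    "build_mmode",
    "extract_wall_trace",
    "measure_dimensions",
    "compute_volumes",
    "compute_ef_fs",
    "find_wall_extrema",
    "wall_velocities",
    "count_heartbeats",
    "analyze_mmode",
]


@dataclass
class MModeImage:
    """Pseudo-linescan matrix: one column per frame, one row per line sample.

    ``positions_px`` are signed offsets (px) along the line from the anchor
    center (the end-systolic center of mass); position 0 is always sampled.
    """

    matrix: np.ndarray
    positions_px: np.ndarray
    axis: str
    angle_deg: float
    center: tuple[float, float]
    pixel_size: float
    fps: float
    times_ms: np.ndarray


@dataclass
class WallTrace:
    """Inner-wall edge positions and lumen width along one M-mode line.

    Edges are the two lumen<->wall transitions nearest the line center,
    located at half-maximum crossings of the smoothed column profile;
    positions are signed micrometres along the line.  ``flags`` marks
    columns where no valid pair of edges was found (values there are
    interpolated).
    """

    times_ms: np.ndarray
    edge_lo_um: np.ndarray     # ventral / negative side
    edge_hi_um: np.ndarray     # dorsal / positive side
    width_um: np.ndarray
    flags: np.ndarray
    axis: str = "short"

    def __post_init__(self) -> None:
        ok = ~self.flags
        if ok.any() and np.any(self.width_um[ok] <= 0):
            raise AnalysisError("lumen width must be positive on valid frames")


@dataclass
class ExtremePoint:
    """One wall-excursion extremum: time (ms), position (um), kind."""

    time_ms: float
    position_um: float
    kind: Literal["inward", "outward"]


@dataclass
class HeartRate:
    """Beat count and rate from a cyclic trace.

    ``bpm`` is derived from the mean inter-beat interval of the detected
    cycle maxima (exact for periodic traces); ``beats`` is the raw count of
    maxima inside the counting window.  ``extrapolated`` is set when the
    trace is shorter than the requested window.
    """

    bpm: float
    beats: int
    window_s: float
    extrapolated: bool


@dataclass
class MModeMetrics:
    """Full M-mode parameter set (dimensions um, volumes pl, rates um/ms)."""

    short_VDs: float
    short_VDd: float
    long_VDs: float
    long_VDd: float
    EDV: float
    ESV: float
    SV: float
    EF: float
    EF_pct: float
    FS_pct: float
    mVWVs: float
    mVWVd: float
    heart_rate_bpm: float
    n_cycles: int
    include_pi: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def build_mmode(
    stack: FrameStack,
    center: tuple[float, float],
    axis: str = "short",
    line_angle_deg: float = 90.0,
) -> MModeImage:
    """Sample a fixed line through ``center`` in every frame.

    The line runs at ``line_angle_deg`` (from +x toward +y) through
    ``center`` and is clipped to the frame bounds; samples are taken at
    1 px spacing with bilinear interpolation (exact row/column extraction
    when the line is axis-aligned and the center coordinate is integral).
    """
    cx, cy = center
    n_rows, n_cols = stack.frame_shape
    if not (0 <= cx <= n_cols - 1 and 0 <= cy <= n_rows - 1):
        raise AnalysisError(f"center {center} outside frame {stack.frame_shape}")

    theta = np.deg2rad(line_angle_deg)
    dx, dy = np.cos(theta), np.sin(theta)

    def reach(d, c, hi):
        """Largest t >= 0 with c + t*d in [0, hi]."""
        if abs(d) < 1e-12:
            return np.inf
        return (hi - c) / d if d > 0 else (0 - c) / d

    t_plus = min(reach(dx, cx, n_cols - 1), reach(dy, cy, n_rows - 1))
    t_minus = min(reach(-dx, cx, n_cols - 1), reach(-dy, cy, n_rows - 1))
    offsets = np.arange(-np.floor(t_minus), np.floor(t_plus) + 1)
    rows = cy + offsets * dy
    cols = cx + offsets * dx

    matrix = np.empty((offsets.size, stack.n_frames))
    for i in range(stack.n_frames):
        matrix[:, i] = ndimage.map_coordinates(
            stack.frames[i].astype(float), [rows, cols], order=1, mode="nearest"
        )
    return MModeImage(
        matrix=matrix,
        positions_px=offsets,
        axis=axis,
        angle_deg=line_angle_deg,
        center=(float(cx), float(cy)),
        pixel_size=stack.pixel_size,
        fps=stack.fps,
        times_ms=stack.times.copy(),
    )


def _column_edges(profile, positions, smooth_sigma_px):
    """Half-maximum edge pair nearest position 0; None if undetectable.

    The half-maximum level is midway between robust floor and peak
    estimates (10th/90th percentile of the smoothed profile), which keeps
    the crossing well defined under noise.
    """
    p = ndimage.gaussian_filter1d(profile, smooth_sigma_px) if smooth_sigma_px > 0 \
        else np.asarray(profile, dtype=float)
    floor = np.percentile(p, 10)
    peak = np.percentile(p, 90)
    if peak - floor <= 0:
        return None
    level = 0.5 * (floor + peak)
    ci = int(np.argmin(np.abs(positions)))
    if p[ci] < level:
        return None  # line center is not inside the bright lumen band

    def cross(direction):
        k = ci
        while 0 <= k + direction < p.size:
            a, b = p[k], p[k + direction]
            if a >= level > b:
                frac = (a - level) / (a - b)
                return positions[k] + direction * frac * abs(
                    positions[k + direction] - positions[k]
                )
            k += direction
        return None

    hi = cross(+1)
    lo = cross(-1)
    if hi is None or lo is None:
        return None  # band runs off the line (uniformly bright)
    return lo, hi


def extract_wall_trace(
    m: MModeImage,
    smooth_sigma_px: float = 1.0,
    max_fail_fraction: float = 0.10,
) -> WallTrace:
    """Per-column lumen edges and width from an M-mode image.

    Columns with no detectable bright band are flagged and linearly
    interpolated from neighbours, provided no more than
    ``max_fail_fraction`` of columns fail.
    """
    n = m.matrix.shape[1]
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    for j in range(n):
        edges = _column_edges(m.matrix[:, j], m.positions_px, smooth_sigma_px)
        if edges is None:
            flags[j] = True
        else:
            lo[j], hi[j] = edges
    n_bad = int(flags.sum())
    if n_bad:
        if n_bad / n > max_fail_fraction:
            raise AnalysisError(
                f"{n_bad}/{n} M-mode columns lack a detectable lumen band"
            )
        warnings.warn(f"interpolating over {n_bad} flagged M-mode column(s)",
                      stacklevel=2)
        idx = np.arange(n)
        for arr in (lo, hi):
            good = ~np.isnan(arr)
            arr[~good] = np.interp(idx[~good], idx[good], arr[good])
    lo_um = lo * m.pixel_size
    hi_um = hi * m.pixel_size
    return WallTrace(
        times_ms=m.times_ms.copy(),
        edge_lo_um=lo_um,
        edge_hi_um=hi_um,
        width_um=hi_um - lo_um,
        flags=flags,
        axis=m.axis,
    )


def _cycle_extrema(values: np.ndarray, prominence_frac: float = 0.25):
    """Indices of per-cycle maxima and minima (prominence-filtered)."""
    values = np.asarray(values, dtype=float)
    amp = np.ptp(values)
    if amp == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    prom = prominence_frac * amp
    maxima, _ = signal.find_peaks(values, prominence=prom)
    minima, _ = signal.find_peaks(-values, prominence=prom)
    return maxima, minima


def measure_dimensions(
    trace: WallTrace | np.ndarray,
    n_cycles: int = 5,
    times_ms: np.ndarray | None = None,
) -> tuple[float, float, dict]:
    """VDs and VDd as means of per-cycle width minima / maxima.

    ``VDs`` averages the first ``n_cycles`` per-cycle minima of the width
    trace and ``VDd`` the first ``n_cycles`` maxima.  If fewer cycles are
    present the available count is used with a warning.  A flat trace
    returns VDs = VDd = mean width.

    Returns ``(VDs, VDd, detail)`` where ``detail`` holds the per-cycle
    extreme values, their times, and the cycle count used.
    """
    if isinstance(trace, WallTrace):
        width = trace.width_um
        times = trace.times_ms
    else:
        width = np.asarray(trace, dtype=float)
        times = (
            np.asarray(times_ms, dtype=float)
            if times_ms is not None
            else np.arange(width.size, dtype=float)
        )
    maxima, minima = _cycle_extrema(width)
    if maxima.size == 0 and minima.size == 0:
        warnings.warn("no cycles detected; VDs = VDd = mean width", stacklevel=2)
        m = float(width.mean())
        return m, m, dict(
            minima_um=[], maxima_um=[], minima_t_ms=[], maxima_t_ms=[], n_cycles=0
        )
    n_avail = min(maxima.size, minima.size)
    if n_avail < n_cycles:
        warnings.warn(
            f"only {n_avail} full cycle(s) available (requested {n_cycles})",
            stacklevel=2,
        )
    n_use = min(n_cycles, n_avail) if n_avail else max(maxima.size, minima.size)
    use_max = maxima[: max(n_use, 1)] if maxima.size else maxima
    use_min = minima[: max(n_use, 1)] if minima.size else minima
    vdd = float(width[use_max].mean()) if use_max.size else float(width.max())
    vds = float(width[use_min].mean()) if use_min.size else float(width.min())
    detail = dict(
        minima_um=width[use_min].tolist(),
        maxima_um=width[use_max].tolist(),
        minima_t_ms=times[use_min].tolist(),
        maxima_t_ms=times[use_max].tolist(),
        n_cycles=int(n_use),
    )
    return vds, vdd, detail


def compute_volumes(
    short_VDs: float,
    short_VDd: float,
    long_VDs: float,
    long_VDd: float,
    include_pi: bool = False,
) -> tuple[float, float, float]:
    """EDV, ESV and SV (pl) from the four M-mode dimensions (um).

    Semi-axes are half the measured internal dimensions; volumes follow the
    prolate-spheroid model (literal ``4ab^2/3`` by default, ``x pi`` with
    ``include_pi``).  A negative SV (physiologically inverted) is returned
    with a warning.
    """
    edv = prolate_volume_pl(long_VDd / 2.0, short_VDd / 2.0, include_pi=include_pi)
    esv = prolate_volume_pl(long_VDs / 2.0, short_VDs / 2.0, include_pi=include_pi)
    sv = edv - esv
    if sv < 0:
        warnings.warn("negative stroke volume (ESV > EDV)", stacklevel=2)
    return edv, esv, sv


def compute_ef_fs(
    EDV: float, ESV: float, short_VDs: float, short_VDd: float
) -> tuple[float, float]:
    """EF = (EDV-ESV)/EDV and %FS = 100(short VDd - short VDs)/short VDd."""
    if EDV <= 0:
        raise AnalysisError("EDV must be positive")
    if short_VDd <= 0:
        raise AnalysisError("short VDd must be positive")
    ef = (EDV - ESV) / EDV
    fs = 100.0 * (short_VDd - short_VDs) / short_VDd
    return float(ef), float(fs)


def find_wall_extrema(
    trace: WallTrace,
    side: str = "ventral",
    n_inward: int = 6,
) -> list[ExtremePoint]:
    """Alternating inward/outward extrema of one wall-edge trace.

    ``side="ventral"`` uses the lower (negative-position) edge; for it,
    inward excursions (end systole) are local maxima of the edge position
    and outward excursions (end diastole) are local minima.  Points are
    returned in time order starting from the first inward point, trimmed to
    at most ``n_inward`` inward + ``n_inward - 1`` outward points (the
    default 6 + 5 reproduces the 11-point scheme).
    """
    edge = trace.edge_lo_um if side == "ventral" else trace.edge_hi_um
    sign = 1.0 if side == "ventral" else -1.0
    e = sign * np.asarray(edge, dtype=float)   # inward = maxima of e
    maxima, minima = _cycle_extrema(e)
    pts = [
        ExtremePoint(float(trace.times_ms[i]), float(edge[i]), "inward")
        for i in maxima
    ] + [
        ExtremePoint(float(trace.times_ms[i]), float(edge[i]), "outward")
        for i in minima
    ]
    pts.sort(key=lambda q: q.time_ms)
    # enforce alternation: among same-kind runs keep the most extreme point
    cleaned: list[ExtremePoint] = []
    for q in pts:
        if cleaned and cleaned[-1].kind == q.kind:
            keep_new = (
                q.position_um > cleaned[-1].position_um
                if (q.kind == "inward") == (sign > 0)
                else q.position_um < cleaned[-1].position_um
            )
            if keep_new:
                cleaned[-1] = q
        else:
            cleaned.append(q)
    while cleaned and cleaned[0].kind != "inward":
        cleaned.pop(0)
    limit = 2 * n_inward - 1
    return cleaned[:limit]


def wall_velocities(
    points: Sequence[ExtremePoint], n_slopes: int = 5
) -> tuple[float, float]:
    """Mean systolic and diastolic wall velocities (um/ms) from extrema.

    Each systolic slope is |dposition/dtime| between a maximal-outward point
    and the following maximal-inward point (wall moving in); each diastolic
    slope spans inward -> outward.  The means of the first ``n_slopes``
    slopes of each kind are returned.  Raises :class:`AnalysisError` if the
    points do not alternate in kind or times are not increasing.
    """
    pts = list(points)
    if len(pts) < 2:
        raise AnalysisError("need at least two extreme points")
    for p, q in zip(pts, pts[1:]):
        if q.time_ms <= p.time_ms:
            raise AnalysisError("extreme-point times must be strictly increasing")
        if q.kind == p.kind:
            raise AnalysisError("extreme points must alternate inward/outward")
    systolic, diastolic = [], []
    for p, q in zip(pts, pts[1:]):
        slope = abs(q.position_um - p.position_um) / (q.time_ms - p.time_ms)
        if p.kind == "outward":        # outward -> inward: contraction
            systolic.append(slope)
        else:                          # inward -> outward: relaxation
            diastolic.append(slope)
    if not systolic or not diastolic:
        raise AnalysisError("need at least one slope of each kind")
    if len(systolic) < n_slopes or len(diastolic) < n_slopes:
        warnings.warn(
            f"averaging {len(systolic)} systolic / {len(diastolic)} diastolic "
            f"slope(s) (requested {n_slopes})",
            stacklevel=2,
        )
    return (
        float(np.mean(systolic[:n_slopes])),
        float(np.mean(diastolic[:n_slopes])),
    )


def count_heartbeats(
    values: np.ndarray,
    times_ms: np.ndarray,
    window_s: float = 15.0,
) -> HeartRate:
    """Heart rate from cycle maxima of a cyclic trace (width or volume).

    Beats are the prominence-filtered peaks inside the first ``window_s``
    seconds.  The rate in bpm comes from the mean inter-beat interval of
    those peaks, which is insensitive to the +/-1-beat phase ambiguity of
    raw counting; when the trace is shorter than the window the result is
    flagged as extrapolated.  A trace with no detectable peaks returns
    0 bpm with a warning.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    dt = float(np.median(np.diff(times)))
    duration_ms = times[-1] - times[0] + dt
    extrapolated = duration_ms < window_s * 1000.0 - 1e-9
    maxima, _ = _cycle_extrema(values)
    in_window = maxima[times[maxima] < times[0] + window_s * 1000.0]
    beats = int(in_window.size)
    if beats == 0:
        warnings.warn("no heartbeat peaks detected", stacklevel=2)
        return HeartRate(0.0, 0, window_s, extrapolated)

    def refined_time(i):
        """Sub-sample peak time by parabolic interpolation of neighbours."""
        if 0 < i < values.size - 1:
            ym, y0, yp = values[i - 1], values[i], values[i + 1]
            denom = ym - 2.0 * y0 + yp
            if denom < 0:
                delta = float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
                return times[i] + delta * dt
        return times[i]

    if beats >= 2:
        span_ms = refined_time(in_window[-1]) - refined_time(in_window[0])
        bpm = 60000.0 * (beats - 1) / span_ms
    else:
        bpm = beats * 60.0 / min(window_s, duration_ms / 1000.0)
    return HeartRate(float(bpm), beats, window_s, bool(extrapolated))


def analyze_mmode(
    stack: FrameStack,
    ellipses: pd.DataFrame | None = None,
    axes: str = "principal",
    include_pi: bool = False,
    n_cycles: int = 5,
    window_s: float = 15.0,
    smooth_sigma_px: float = 1.0,
    enhance_method: str = "none",
    enhance_params: dict | None = None,
    threshold_method: str | float = "otsu",
    min_area_px: int = 25,
) -> MModeMetrics:
    """Full M-mode pipeline: segment, build M-modes, measure everything.

    The M-mode anchor is the center of mass of the reference end-systolic
    frame (the frame with the smallest lumen area).  With ``axes=
    "principal"`` (default) the long/short lines follow the principal axes
    of that frame's ellipse; ``axes="image"`` uses strict horizontal /
    vertical lines.
    """
    if ellipses is None:
        ellipses = fit_stack(
            stack,
            enhance_method=enhance_method,
            enhance_params=enhance_params,
            threshold_method=threshold_method,
            min_area_px=min_area_px,
        )
    ref = ellipses.loc[ellipses["area_px"].idxmin()]
    center = (float(ref["cx"]), float(ref["cy"]))
    long_angle = float(ref["theta_deg"]) if axes == "principal" else 0.0
    short_angle = long_angle + 90.0

    m_long = build_mmode(stack, center, axis="long", line_angle_deg=long_angle)
    m_short = build_mmode(stack, center, axis="short", line_angle_deg=short_angle)
    tr_long = extract_wall_trace(m_long, smooth_sigma_px=smooth_sigma_px)
    tr_short = extract_wall_trace(m_short, smooth_sigma_px=smooth_sigma_px)

    long_vds, long_vdd, _ = measure_dimensions(tr_long, n_cycles=n_cycles)
    short_vds, short_vdd, _ = measure_dimensions(tr_short, n_cycles=n_cycles)

    edv, esv, sv = compute_volumes(
        short_vds, short_vdd, long_vds, long_vdd, include_pi=include_pi
    )
    ef, fs = compute_ef_fs(edv, esv, short_vds, short_vdd)

    pts = find_wall_extrema(tr_short, side="ventral", n_inward=n_cycles + 1)
    mvwvs, mvwvd = wall_velocities(pts, n_slopes=n_cycles)

    hr = count_heartbeats(tr_short.width_um, tr_short.times_ms, window_s=window_s)

    return MModeMetrics(
        short_VDs=short_vds,
        short_VDd=short_vdd,
        long_VDs=long_vds,
        long_VDd=long_vdd,
        EDV=edv,
        ESV=esv,
        SV=sv,
        EF=ef,
        EF_pct=100.0 * ef,
        FS_pct=fs,
        mVWVs=mvwvs,
        mVWVd=mvwvd,
        heart_rate_bpm=hr.bpm,
        n_cycles=n_cycles,
        include_pi=include_pi,
    )
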