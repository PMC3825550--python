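"""Time-volume-curve (TVC) analysis via truncated Fourier series.

The per-frame ventricular volume (from each frame's best-fitting-ellipse
axes and the prolate-spheroid model) is fitted with a five-harmonic Fourier
series over the cardiac cycle,

    v(t) = a0 + sum_{k=1..K} [ a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T) ],

whose term-wise analytic derivative is the differentiation curve.  All
printed TVC parameters derive from the fitted pair:

========  =====================================================
V1 / V2   end-diastolic / end-systolic volume (curve max / min)
V3 / V4   volume one third into ejection / filling
D1 / D2   peak ejection (most negative) / filling (most positive) dv/dt
D3 / D4   mean dv/dt over the first third of ejection / filling
TD1, TD2  time from end-diastole to D1 (TPE) / end-systole to D2 (TPF)
========  =====================================================

with EF% = 100 (V1 - V2)/V1, 1/3EF% = 100 (V1 - V3)/V1,
1/3FF% = 100 (V4 - V2)/(V1 - V2), PER = -D1 x 1000 / V1,
PFR = D2 x 1000 / V1, 1/3ER = -D3 x 1000 / V1 and 1/3FR = D4 x 1000 / V1
(an alternative literal normalisation of 1/3FR by T x V1 is available via a
flag).  Raw (un-normalised) peak rates in pl/ms are emitted alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import AnalysisError
from .io import FrameStack
from .segmentation import fit_stack
from .volume import prolate_volume_pl

__all__ = [
    "VolumeSeries",
    "FourierFit",
    "TVCMetrics",
    "volume_series",
    "estimate_fundamental",
    "fourier_fit",
    "tvc_parameters",
    "analyze_tvc",
]

#: dense-grid resolution (samples per period) used when locating extrema
GRID_N = 2048


@dataclass
class VolumeSeries:
    """Per-frame ventricular volume: times (ms) and volumes (pl)."""

    times_ms: np.ndarray
    volumes_pl: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.volumes_pl = np.asarray(self.volumes_pl, dtype=float)
        if self.times_ms.shape != self.volumes_pl.shape:
            raise AnalysisError("times and volumes must have the same length")
        if np.any(self.volumes_pl <= 0):
            raise AnalysisError("volumes must be positive")

    def __len__(self) -> int:
        return self.times_ms.size


@dataclass
class FourierFit:
    """Truncated Fourier series fitted to a volume series.

    ``a`` / ``b`` are the cosine / sine coefficients for harmonics 1..K;
    the fitted curve is infinitely differentiable and T-periodic, and
    :meth:`derivative` is its exact term-wise derivative.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    period_ms: float
    residual_rms: float
    n_samples: int

    @property
    def n_harmonics(self) -> int:
        return self.a.size

    def evaluate(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        w = 2.0 * np.pi / self.period_ms
        k = np.arange(1, self.n_harmonics + 1)
        phase = np.multiply.outer(t, k) * w
        out = self.a0 + np.cos(phase) @ self.a + np.sin(phase) @ self.b
        return float(out) if np.isscalar(t_ms) else out

    def derivative(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        w = 2.0 * np.pi / self.period_ms
        k = np.arange(1, self.n_harmonics + 1)
        phase = np.multiply.outer(t, k) * w
        out = -np.sin(phase) @ (self.a * k * w) + np.cos(phase) @ (self.b * k * w)
        return float(out) if np.isscalar(t_ms) else out


@dataclass
class TVCMetrics:
    """The full printed TVC parameter set (volumes pl, times ms)."""

    V1: float
    V2: float
    V3: float
    V4: float
    D1: float
    D2: float
    D3: float
    D4: float
    TD1: float                 # = TPE (ms)
    TD2: float                 # = TPF (ms)
    EF_pct: float
    one_third_EF_pct: float
    one_third_FF_pct: float
    one_third_ER: float
    PER: float
    one_third_FR: float
    PFR: float
    PER_raw_pl_ms: float
    PFR_raw_pl_ms: float
    T_ms: float
    t_ED_ms: float
    t_ES_ms: float

    # aliases for the clinical names
    @property
    def TPE_ms(self) -> float:
        return self.TD1

    @property
    def TPF_ms(self) -> float:
        return self.TD2

    def to_dict(self) -> dict:
        return asdict(self)


def volume_series(
    ellipses: pd.DataFrame,
    pixel_size: float,
    times_ms: np.ndarray | None = None,
    fps: float | None = None,
    include_pi: bool = False,
) -> VolumeSeries:
    """Per-frame volumes from ellipse fits (``a_px``/``b_px`` columns).

    Semi-axes are converted to micrometres via ``pixel_size`` and volumes
    computed with the configured prolate formula.  Timestamps come from
    ``times_ms`` or are derived from ``fps``.
    """
    a_um = ellipses["a_px"].to_numpy(dtype=float) * pixel_size
    b_um = ellipses["b_px"].to_numpy(dtype=float) * pixel_size
    if np.any(~np.isfinite(a_um)) or np.any(~np.isfinite(b_um)):
        raise AnalysisError("ellipse table contains missing axes")
    if np.any(a_um <= 0) or np.any(b_um <= 0):
        raise AnalysisError("ellipse axes must be positive (zero-area frame?)")
    if times_ms is None:
        if fps is None:
            raise AnalysisError("need times_ms or fps")
        times_ms = ellipses["frame"].to_numpy(dtype=float) * 1000.0 / fps
    vols = prolate_volume_pl(a_um, b_um, include_pi=include_pi)
    return VolumeSeries(times_ms=np.asarray(times_ms, dtype=float), volumes_pl=vols)


def estimate_fundamental(vs: VolumeSeries) -> float:
    """Cardiac period (ms) from the dominant spectral peak of the series.

    The discrete spectrum of the mean-subtracted series is searched for its
    largest nonzero-frequency magnitude; the peak location is refined by
    local quadratic interpolation of the magnitude.  Requires at least two
    cycles of data; a flat series raises :class:`AnalysisError`.
    """
    v = vs.volumes_pl - vs.volumes_pl.mean()
    if np.ptp(v) <= 1e-12 * max(1.0, abs(vs.volumes_pl.mean())):
        raise AnalysisError("flat volume series: no fundamental frequency")
    dt = np.diff(vs.times_ms)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * dt[0]):
        raise AnalysisError("spectral period estimation needs uniform sampling")
    dt_ms = float(dt[0])
    n = v.size
    mag = np.abs(np.fft.rfft(v))
    if mag.size < 3:
        raise AnalysisError("series too short for period estimation")
    k = int(np.argmax(mag[1:])) + 1
    # quadratic refinement of the peak bin
    if 1 <= k < mag.size - 1:
        ym, y0, yp = mag[k - 1], mag[k], mag[k + 1]
        denom = ym - 2.0 * y0 + yp
        delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq_per_ms = (k + delta) / (n * dt_ms)
    period = 1.0 / freq_per_ms
    duration = n * dt_ms
    if period > duration / 2.0 * (1.0 + 1e-9):
        raise AnalysisError(
            f"estimated period {period:.1f} ms implies fewer than two cycles "
            f"in the {duration:.1f} ms record"
        )
    return float(period)


def fourier_fit(vs: VolumeSeries, period_ms: float, K: int = 5) -> FourierFit:
    """Least-squares fit of a K-harmonic Fourier series at a known period.

    Fewer than ``2K + 1`` samples raise :class:`AnalysisError`.  When a
    harmonic falls exactly on the sampling Nyquist frequency (e.g. a 500 ms
    cycle sampled at 20 fps puts the 5th harmonic at 10 Hz) its sine column
    vanishes and the design loses rank; the minimum-norm least-squares
    solution is then used (the unobservable coefficient is set to zero)
    with a warning.
    """
    n = len(vs)
    if n < 2 * K + 1:
        raise AnalysisError(f"need >= {2 * K + 1} samples for K={K} harmonics")
    w = 2.0 * np.pi / period_ms
    k = np.arange(1, K + 1)
    phase = np.multiply.outer(vs.times_ms, k) * w
    design = np.hstack([np.ones((n, 1)), np.cos(phase), np.sin(phase)])
    coef, _, rank, _ = np.linalg.lstsq(design, vs.volumes_pl, rcond=None)
    if rank < 2 * K + 1:
        warnings.warn(
            f"Fourier design is rank deficient ({rank} < {2 * K + 1}); "
            "harmonic at the Nyquist frequency - using the minimum-norm fit",
            stacklevel=2,
        )
    resid = vs.volumes_pl - design @ coef
    return FourierFit(
        a0=float(coef[0]),
        a=coef[1 : K + 1].copy(),
        b=coef[K + 1 :].copy(),
        period_ms=float(period_ms),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_samples=n,
    )


def _refine(func, t0: float, h: float):
    """Locate the minimum of ``func`` within +/- h of grid point t0."""
    res = optimize.minimize_scalar(
        func, bounds=(t0 - h, t0 + h), method="bounded",
        options={"xatol": 1e-9 * max(abs(t0), h, 1.0)},
    )
    return float(res.x), float(res.fun)


def tvc_parameters(fit: FourierFit, one_third_fr_literal: bool = False) -> TVCMetrics:
    """All TVC parameters from a fitted curve and its analytic derivative.

    End-diastole ``t_ED`` is the global maximum of the fitted curve over one
    period (earliest of ties) and end-systole ``t_ES`` the following global
    minimum; ejection spans ``[t_ED, t_ES]`` and filling ``[t_ES, t_ED + T]``.
    Extrema are located on a dense T/2048 grid and refined by bounded local
    optimisation of the analytic curve.  A curve without distinct extrema
    (zero oscillation) raises :class:`AnalysisError`.

    ``one_third_fr_literal`` switches 1/3FR from ``D4 x 1000 / V1`` to the
    literal printed normalisation ``D4 x 1000 / (T x V1)``.
    """
    T = fit.period_ms
    tg = np.linspace(0.0, T, GRID_N, endpoint=False)
    vg = fit.evaluate(tg)
    amp = float(vg.max() - vg.min())
    if amp <= 1e-9 * max(1.0, abs(fit.a0)):
        raise AnalysisError("fitted curve has no distinct extrema (flat)")
    h = T / GRID_N

    i_ed = int(np.argmax(vg))                     # earliest tie wins (argmax)
    t_ed, neg_v1 = _refine(lambda t: -fit.evaluate(t), tg[i_ed], h)
    v1 = -neg_v1
    t_ed = t_ed % T

    # end-systole: global minimum, placed after t_ED within one period
    i_es = int(np.argmin(vg))
    t_es0, v2 = _refine(fit.evaluate, tg[i_es], h)
    te = (t_es0 - t_ed) % T                       # ejection duration
    if te == 0:
        raise AnalysisError("degenerate cycle: coincident extrema")
    t_es = t_ed + te
    tf = T - te                                   # filling duration

    v3 = fit.evaluate(t_ed + te / 3.0)
    v4 = fit.evaluate(t_es + tf / 3.0)

    # peak rates from the analytic derivative, restricted to each phase
    ej = np.linspace(t_ed, t_es, GRID_N)
    dej = fit.derivative(ej)
    i1 = int(np.argmin(dej))
    t1, d1 = _refine(fit.derivative, ej[i1], (t_es - t_ed) / GRID_N)
    t1 = min(max(t1, t_ed), t_es)

    fi = np.linspace(t_es, t_ed + T, GRID_N)
    dfi = fit.derivative(fi)
    i2 = int(np.argmax(dfi))
    t2, neg_d2 = _refine(lambda t: -fit.derivative(t), fi[i2], (t_ed + T - t_es) / GRID_N)
    d2 = -neg_d2
    t2 = min(max(t2, t_es), t_ed + T)

    d3 = (v3 - v1) / (te / 3.0)
    d4 = (v4 - v2) / (tf / 3.0)

    if v1 <= 0:
        raise AnalysisError("non-positive end-diastolic volume")
    ef = 100.0 * (v1 - v2) / v1
    one_third_ef = 100.0 * (v1 - v3) / v1
    one_third_ff = 100.0 * (v4 - v2) / (v1 - v2)
    per = -d1 * 1000.0 / v1
    pfr = d2 * 1000.0 / v1
    one_third_er = -d3 * 1000.0 / v1
    one_third_fr = (
        d4 * 1000.0 / (T * v1) if one_third_fr_literal else d4 * 1000.0 / v1
    )

    return TVCMetrics(
        V1=float(v1),
        V2=float(v2),
        V3=float(v3),
        V4=float(v4),
        D1=float(d1),
        D2=float(d2),
        D3=float(d3),
        D4=float(d4),
        TD1=float(t1 - t_ed),
        TD2=float(t2 - t_es),
        EF_pct=float(ef),
        one_third_EF_pct=float(one_third_ef),
        one_third_FF_pct=float(one_third_ff),
        one_third_ER=float(one_third_er),
        PER=float(per),
        one_third_FR=float(one_third_fr),
        PFR=float(pfr),
        PER_raw_pl_ms=float(-d1),
        PFR_raw_pl_ms=float(d2),
        T_ms=float(T),
        t_ED_ms=float(t_ed),
        t_ES_ms=float(t_es),
    )


def analyze_tvc(
    stack: FrameStack,
    ellipses: pd.DataFrame | None = None,
    period_ms: float | None = None,
    K: int = 5,
    include_pi: bool = False,
    one_third_fr_literal: bool = False,
    enhance_method: str = "none",
    enhance_params: dict | None = None,
    threshold_method: str | float = "otsu",
    min_area_px: int = 25,
) -> tuple[TVCMetrics, FourierFit, VolumeSeries]:
    """Full TVC pipeline: segment, build the volume series, fit, measure."""
    if ellipses is None:
        ellipses = fit_stack(
            stack,
            enhance_method=enhance_method,
            enhance_params=enhance_params,
            threshold_method=threshold_method,
            min_area_px=min_area_px,
        )
    vs = volume_series(
        ellipses, stack.pixel_size, times_ms=stack.times, include_pi=include_pi
    )
    if period_ms is None:
        period_ms = estimate_fundamental(vs)
    fit = fourier_fit(vs, period_ms, K=K)
    metrics = tvc_parameters(fit, one_third_fr_literal=one_third_fr_literal)
    return metrics, fit, vs
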