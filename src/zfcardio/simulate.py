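"""Synthetic beating-ventricle videos and morphant cohorts with ground truth.

This module forward-simulates the two kinds of data the analysis stages
consume, so every stage can be validated against a known answer:

* :func:`simulate_beating_ventricle` renders a fluorescently bright elliptical
  lumen (the dye-filled plasma) surrounded by a darker wall ring on a dim
  background, contracting periodically between end-diastolic and end-systolic
  semi-axes.  The contraction profile ``s(t)`` is a C1 raised-cosine: systole
  (0 -> 1) over ``systole_fraction`` of the period, then relaxation (1 -> 0)
  over the remainder.  Edges are rendered with 4x supersampling, then Gaussian
  blur and additive Gaussian noise are applied, in that order.  The paired
  :class:`GroundTruth` carries the analytic per-frame axes, centers and
  volumes plus the scalar cardiac parameters.

* :func:`simulate_morphant_cohort` draws a cohort of morpholino-injected
  embryos whose lissamine fluorescence intensity (FI, the per-embryo dose
  proxy) is log-normal and whose target-gene expression decays as
  ``exp(-k * FI)`` with multiplicative log-normal noise; a phenotype class is
  assigned by thresholding true expression.

All randomness flows through a single integer seed; identical parameters and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .io import FrameStack
from .volume import prolate_volume_pl

__all__ = [
    "BeatParams",
    "GroundTruth",
    "MorphantCohortParams",
    "simulate_beating_ventricle",
    "simulate_morphant_cohort",
    "raised_cosine_profile",
]


def raised_cosine_profile(t_ms, period_ms: float, systole_fraction: float):
    """Contraction profile s(t) in [0, 1] and its derivative ds/dt (1/ms).

    s rises 0 -> 1 over the systolic interval ``[0, f*T)`` as a raised cosine
    and falls 1 -> 0 over ``[f*T, T)``; the derivative vanishes at both ends
    of each half so the profile is C1-periodic.  t = 0 is end-diastole.
    """
    t = np.asarray(t_ms, dtype=float) % period_ms
    ts = systole_fraction * period_ms
    td = period_ms - ts
    s = np.where(
        t < ts,
        0.5 * (1.0 - np.cos(np.pi * t / ts)),
        0.5 * (1.0 + np.cos(np.pi * (t - ts) / td)),
    )
    ds = np.where(
        t < ts,
        0.5 * np.pi / ts * np.sin(np.pi * t / ts),
        -0.5 * np.pi / td * np.sin(np.pi * (t - ts) / td),
    )
    return s, ds


_WAVEFORMS: dict[str, Callable] = {"raised_cosine": raised_cosine_profile}


@dataclass
class BeatParams:
    """Parameters of the simulated beating ventricle.

    Lengths are micrometres, times milliseconds, intensities camera counts.
    Defaults describe a 60-hpf-like ventricle: 100 x 60 um end-diastolic
    lumen contracting to 80 x 42 um at 2 Hz (EF ~ 0.61 under the literal
    prolate formula).
    """

    period_ms: float = 500.0
    a_ED: float = 50.0          # end-diastolic long semi-axis (um)
    b_ED: float = 30.0          # end-diastolic short semi-axis (um)
    a_ES: float = 40.0          # end-systolic long semi-axis (um)
    b_ES: float = 21.0          # end-systolic short semi-axis (um)
    systole_fraction: float = 0.4
    waveform: str = "raised_cosine"
    orientation_deg: float = 0.0
    drift_um_s: tuple[float, float] = (0.0, 0.0)   # center drift (x, y)
    wall_um: float = 4.0        # wall-ring thickness
    I_lumen: float = 1000.0
    I_wall: float = 300.0
    I_bg: float = 50.0
    noise_sd: float = 0.0
    blur_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a_ED > self.a_ES > 0 and self.b_ED > self.b_ES > 0):
            raise ParameterError("need a_ED > a_ES > 0 and b_ED > b_ES > 0")
        if not self.period_ms > 0:
            raise ParameterError("period_ms must be positive")
        if not 0 < self.systole_fraction < 1:
            raise ParameterError("systole_fraction must be in (0, 1)")
        if not (self.I_lumen > self.I_wall >= self.I_bg >= 0):
            raise ParameterError("need I_lumen > I_wall >= I_bg >= 0")
        if self.noise_sd < 0 or self.blur_sigma_px < 0 or self.wall_um < 0:
            raise ParameterError("noise_sd, blur_sigma_px, wall_um must be >= 0")
        if self.waveform not in _WAVEFORMS:
            raise ParameterError(f"unknown waveform {self.waveform!r}")


@dataclass
class GroundTruth:
    """Analytic truth paired with a simulated stack.

    Per-frame arrays are evaluated at the frame timestamps; scalar
    parameters come from the end-diastolic/end-systolic axes and the
    analytic waveform, with peak rates from the analytic derivative of the
    true volume curve.  Volumes use the configured prolate formula (pl).
    """

    times_ms: np.ndarray
    a_um: np.ndarray
    b_um: np.ndarray
    center_px: np.ndarray       # (n_frames, 2) as (x, y)
    volume_pl: np.ndarray
    EDV_pl: float
    ESV_pl: float
    SV_pl: float
    EF: float
    FS_pct: float
    heart_rate_bpm: float
    peak_ejection_rate_pl_ms: float   # max of -dV/dt (positive)
    peak_filling_rate_pl_ms: float    # max of +dV/dt (positive)
    period_ms: float
    include_pi: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def _axes_at(p: BeatParams, t_ms):
    s, ds = _WAVEFORMS[p.waveform](t_ms, p.period_ms, p.systole_fraction)
    a = p.a_ED - (p.a_ED - p.a_ES) * s
    b = p.b_ED - (p.b_ED - p.b_ES) * s
    da = -(p.a_ED - p.a_ES) * ds
    db = -(p.b_ED - p.b_ES) * ds
    return a, b, da, db


def _true_peak_rates(p: BeatParams, include_pi: bool) -> tuple[float, float]:
    """Peak |dV/dt| during ejection and filling of the analytic volume curve."""
    t = np.linspace(0.0, p.period_ms, 20001)
    a, b, da, db = _axes_at(p, t)
    scale = prolate_volume_pl(1.0, 1.0, include_pi=include_pi)  # pl per um^3 factor
    dv = scale * (da * b * b + 2.0 * a * b * db)                # pl/ms
    return float(-dv.min()), float(dv.max())


def simulate_beating_ventricle(
    p: BeatParams,
    n_frames: int = 60,
    fps: float = 20.0,
    pixel_size: float = 1.0,
    image_shape: tuple[int, int] = (128, 128),
    include_pi: bool = False,
    supersample: int = 4,
) -> tuple[FrameStack, GroundTruth]:
    """Render a beating-ventricle stack and its analytic ground truth.

    The lumen ellipse (intensity ``I_lumen``) sits inside a wall ring of
    thickness ``wall_um`` (``I_wall``) on an ``I_bg`` background.  Raises
    :class:`ParameterError` if the end-diastolic ellipse plus wall ring does
    not fit inside the frame (allowing for drift over the recording).

    Returns a ``(FrameStack, GroundTruth)`` pair; frames are uint16.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rows, cols = image_shape
    times = np.arange(n_frames) * 1000.0 / fps

    cx0, cy0 = (cols - 1) / 2.0, (rows - 1) / 2.0
    drift = np.asarray(p.drift_um_s, dtype=float) / pixel_size / 1000.0  # px/ms
    centers = np.stack([cx0 + drift[0] * times, cy0 + drift[1] * times], axis=1)

    outer_px = (p.a_ED + p.wall_um) / pixel_size
    for cx, cy in (centers[0], centers[-1]):
        if (
            cx - outer_px < 0 or cx + outer_px > cols - 1
            or cy - outer_px < 0 or cy + outer_px > rows - 1
        ):
            raise ParameterError(
                "end-diastolic ellipse plus wall ring exceeds the frame; "
                "enlarge image_shape or shrink the ventricle"
            )

    a_t, b_t, _, _ = _axes_at(p, times)

    # supersampled pixel-center grid (pixel centers at integers)
    ss = supersample
    xs = (np.arange(cols * ss) - (ss - 1) / 2.0) / ss
    ys = (np.arange(rows * ss) - (ss - 1) / 2.0) / ss
    X, Y = np.meshgrid(xs, ys)
    theta = np.deg2rad(p.orientation_deg)
    ct, st = np.cos(theta), np.sin(theta)

    rng = np.random.default_rng(p.seed)
    frames = np.empty((n_frames, rows, cols), dtype=np.uint16)
    for i in range(n_frames):
        cx, cy = centers[i]
        u = (X - cx) * ct + (Y - cy) * st
        v = -(X - cx) * st + (Y - cy) * ct
        a_px = a_t[i] / pixel_size
        b_px = b_t[i] / pixel_size
        w_px = p.wall_um / pixel_size
        r_in = (u / a_px) ** 2 + (v / b_px) ** 2
        r_out = (u / (a_px + w_px)) ** 2 + (v / (b_px + w_px)) ** 2
        img = np.full(X.shape, p.I_bg)
        img[r_out <= 1.0] = p.I_wall
        img[r_in <= 1.0] = p.I_lumen
        # average supersampled blocks back to the target grid
        img = img.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
        if p.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, p.blur_sigma_px)
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    stack = FrameStack(frames=frames, fps=fps, pixel_size=pixel_size)

    edv = prolate_volume_pl(p.a_ED, p.b_ED, include_pi=include_pi)
    esv = prolate_volume_pl(p.a_ES, p.b_ES, include_pi=include_pi)
    per, pfr = _true_peak_rates(p, include_pi)
    truth = GroundTruth(
        times_ms=times,
        a_um=a_t,
        b_um=b_t,
        center_px=centers,
        volume_pl=prolate_volume_pl(a_t, b_t, include_pi=include_pi),
        EDV_pl=edv,
        ESV_pl=esv,
        SV_pl=edv - esv,
        EF=(edv - esv) / edv,
        FS_pct=100.0 * (p.b_ED - p.b_ES) / p.b_ED,
        heart_rate_bpm=60000.0 / p.period_ms,
        peak_ejection_rate_pl_ms=per,
        peak_filling_rate_pl_ms=pfr,
        period_ms=p.period_ms,
        include_pi=include_pi,
    )
    return stack, truth


@dataclass
class MorphantCohortParams:
    """Parameters of a simulated morpholino-dose cohort.

    FI (lissamine fluorescence intensity, arbitrary units) is log-normal
    across injected embryos; true expression of the targeted transcript is
    ``exp(-knockdown_slope * FI)`` and the measured expression ratio carries
    multiplicative log-normal noise.  Phenotype severity is assigned by
    thresholding true expression: below ``thresholds[0]`` -> no cardiac
    output, below ``thresholds[1]`` -> congestion, else no phenotype.
    ``n_controls`` uninjected-dose controls (FI uniform on [0, 1), expression
    ~ 1) are appended so normalisation against low-FI controls is always
    possible.
    """

    n: int = 300
    fi_log_mean: float = 1.4      # log FI ~ N(1.4, 0.6): median FI ~ 4
    fi_log_sd: float = 0.6
    knockdown_slope: float = 0.15
    noise_log_sd: float = 0.15
    thresholds: tuple[float, float] = (0.3, 0.6)
    n_controls: int = 20
    group: str = "morphant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ParameterError("phenotype thresholds must be increasing")
        if self.knockdown_slope < 0 or self.noise_log_sd < 0:
            raise ParameterError("knockdown_slope and noise_log_sd must be >= 0")


PHENOTYPES = ("no_phenotype", "congestion", "no_cardiac_output")


def _classify(expr_true: np.ndarray, thresholds: tuple[float, float]) -> np.ndarray:
    lo, hi = thresholds
    out = np.where(
        expr_true < lo, "no_cardiac_output",
        np.where(expr_true < hi, "congestion", "no_phenotype"),
    )
    return out


def simulate_morphant_cohort(p: MorphantCohortParams) -> pd.DataFrame:
    """Draw one morphant cohort as a tidy DataFrame.

    Columns: ``id, group, FI, expression_true, expression_ratio, phenotype``.
    Expression is non-increasing in FI in expectation (exactly 1 everywhere
    when ``knockdown_slope=0`` and ``noise_log_sd=0``).  Fixed seed gives an
    identical table.
    """
    rng = np.random.default_rng(p.seed)
    fi = rng.lognormal(p.fi_log_mean, p.fi_log_sd, size=p.n)
    expr_true = np.exp(-p.knockdown_slope * fi)
    noise = (
        rng.lognormal(0.0, p.noise_log_sd, size=p.n)
        if p.noise_log_sd > 0
        else np.ones(p.n)
    )
    expr = expr_true * noise

    fi_ctrl = rng.uniform(0.0, 1.0, size=p.n_controls)
    expr_ctrl_true = np.exp(-p.knockdown_slope * fi_ctrl)
    noise_ctrl = (
        rng.lognormal(0.0, p.noise_log_sd, size=p.n_controls)
        if p.noise_log_sd > 0
        else np.ones(p.n_controls)
    )

    df = pd.DataFrame(
        {
            "id": [f"{p.group}-{i:04d}" for i in range(p.n)]
            + [f"control-{i:04d}" for i in range(p.n_controls)],
            "group": [p.group] * p.n + ["control"] * p.n_controls,
            "FI": np.concatenate([fi, fi_ctrl]),
            "expression_true": np.concatenate([expr_true, expr_ctrl_true]),
            "expression_ratio": np.concatenate([expr, expr_ctrl_true * noise_ctrl]),
        }
    )
    df["phenotype"] = _classify(df["expression_true"].to_numpy(), p.thresholds)
    return df
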