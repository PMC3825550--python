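# Methods

This note documents the models, conventions and numerical choices behind
`zfcardio`, in the order data flows through the package.

## Conventions

Pixel coordinates are 0-based with `x` along columns and `y` along rows;
pixel centers sit at integer coordinates.  Areas in px² convert to um²
via `pixel_size²`.  Frame timestamps are derived as `index / fps`
(uniform timing) unless explicit times are supplied; widefield cameras in
this setting deliver approximately constant frame intervals and no
per-frame stamps.  Volumes are reported in picolitres (1 pl = 10³ um³).
Native 8/16-bit integer frames are kept as acquired in memory so a write /
read cycle through multi-page TIFF is bit-identical; all computation
promotes to float64.

## Segmentation and the best-fitting ellipse

The dye-filled lumen is the brightest region of each frame.  The default
delineation is: optional enhancement (identity, Gaussian denoise,
large-scale background subtraction, or Richardson-Lucy deblurring with a
Gaussian PSF - the appropriate strength depends on the optics, so it is
configuration rather than a fixed step), Otsu or fixed threshold, largest
connected component with a minimum area, hole filling.  This automates the
manual outline-the-lumen workflow; manually traced polygons remain a
first-class input and bypass thresholding entirely.

The "best fitting ellipse" is moment-matched: it shares the region's
centroid and principal second central moments, and its semi-axes are then
rescaled by a common factor so that ellipse area equals region area
exactly (the classic ImageJ construction, chosen over contour
least-squares because the established workflow this package automates is
moment-based).  For traced polygons the moments are evaluated in closed
form by Green's theorem, avoiding rasterisation error.  Orientation is
reported in [0°, 180°) from the +x axis; an exact circle reports 0° by
convention.  Frames where segmentation fails are flagged and linearly
interpolated from neighbours when at most 10 % of frames fail; more than
that aborts the analysis.

## M-mode analysis

The anchor is the center of mass of the reference end-systolic frame (the
frame of minimal lumen area).  By default the long/short M-mode lines
follow the principal axes of that frame's ellipse, generalising strict
horizontal/vertical lines to arbitrarily mounted embryos; `axes="image"`
restores the horizontal/vertical convention.  Lines are sampled at 1 px
spacing with bilinear interpolation (axis-aligned lines through integral
centers reduce to exact row/column extraction).

Wall edges per M-mode column are the two lumen-to-wall transitions nearest
the line center, located at half-maximum crossings of the Gaussian-smoothed
(sigma = 1 px) profile with sub-pixel linear interpolation.  The
half-maximum level is midway between robust floor and peak estimates
(10th/90th percentiles of the column profile) rather than the raw min/max;
this leaves noise-free behaviour unchanged and keeps the crossing well
defined at low signal-to-noise.  Columns without a detectable band
(line entirely inside or outside the lumen) are flagged and interpolated
under the same 10 % policy.

`VDs`/`VDd` average the per-cycle minima/maxima of the width trace over
five cycles by default (fewer cycles are used with a warning).  Cycle
extrema are prominence-filtered peaks (prominence = 25 % of the trace
range), ties broken by earliest time.  Wall velocities follow the 11-point
scheme: alternating maximal-inward (6) and maximal-outward (5) excursions
of the ventral wall edge give five systolic (outward->inward) and five
diastolic (inward->outward) slopes whose means are `mVWVs` and `mVWVd`
in um/ms; the scheme generalises to n cycles with n+1 inward / n outward
points.

Heart rate counts cycle maxima in a 15 s window.  Because integer peak
counts carry a +/-1-beat phase ambiguity at the trace boundaries (up to
4 bpm at 15 s), the reported bpm comes from the mean inter-beat interval
of the detected peaks, with peak times refined to sub-frame precision by
parabolic interpolation; the raw beat count is reported alongside.  Traces
shorter than the window yield a rate flagged as extrapolated.

## Volumes

The prolate-spheroid volume is computed literally as `V = 4 a b² / 3`
(`a`, `b` = long/short semi-axes in um), the form printed in the workflow
this package reproduces; whether the omission of pi there is intentional
cannot be resolved from the text, so the geometric volume
`(4/3) pi a b²` is available behind `include_pi=True`.  All volume-derived
quantities (EF, SV, TVC parameters) are ratios or differences, so the
choice cancels from EF and only rescales absolute volumes.

## Time-volume-curve analysis

Per-frame volumes from the ellipse axes form the TVC.  The cardiac period
is estimated from the dominant nonzero-frequency peak of the discrete
spectrum of the mean-subtracted series, refined by local quadratic
interpolation of the magnitude; the user can override it.  A five-harmonic
Fourier series (K configurable) is fitted by linear least squares.  When a
harmonic falls exactly on the sampling Nyquist frequency (a 500 ms cycle at
20 fps puts the 5th harmonic at 10 Hz) its sine column vanishes; the
minimum-norm solution is used and a warning emitted, since this is the
normal operating regime at ~20 fps rather than an error.

Parameters are read off one period of the fitted curve and its term-wise
analytic derivative.  End-diastole `t_ED` is the global maximum (earliest
of ties), end-systole `t_ES` the following global minimum; ejection spans
`[t_ED, t_ES]` and filling `[t_ES, t_ED + T]`.  `V3`/`V4` are the volumes
one third into each phase; `D1`/`D2` the extreme derivative on each phase
with `TD1`/`TD2` their latencies from phase onset; `D3`/`D4` the mean
derivative over the first third of each phase.  Extrema are located on a
T/2048 grid and refined by bounded scalar optimisation of the analytic
curve, giving deterministic sub-millisecond accuracy.  Derived indices:
`EF% = 100(V1-V2)/V1`, `1/3EF% = 100(V1-V3)/V1`, `1/3FF% =
100(V4-V2)/(V1-V2)`, `1/3ER = -D3*1000/V1`, `PER = -D1*1000/V1`, `PFR =
D2*1000/V1`.  The printed definition of `1/3FR` (`D4*1000/T*V1`) is
dimensionally inconsistent with its ejection counterpart; the default here
is the symmetric `D4*1000/V1`, with the literal reading
`D4*1000/(T*V1)` behind a flag.  Because the x1000/V1 normalisation
yields units of 1/s rather than pl/ms, the raw peak rates in pl/ms are
emitted alongside the normalised ones.

## Dose-response statistics

FI bins are half-open with inclusive lower edges - `FI < 2`,
`2 <= FI < 4`, `4 <= FI < 8`, `FI >= 8` - and expression ratios are
normalised by the mean ratio of the `FI < 1` control subset.  Spearman's
rank correlation uses average ranks for ties; its two-sided p-value is the
exact permutation probability for n <= 9 (vectorised over all n!
permutations) and the t approximation on n-2 df otherwise.  Group
comparisons use the pooled-variance two-sided Student's t test (Welch via
flag), with Bonferroni adjustment `min(1, p * m)` over the m pairs
actually tested - the most common reading of a "Bonferroni multiple
comparisons test", flagged as such in the output.  The 2x2 chi-square is
Pearson's without continuity correction by default (the uncorrected test
is what the named "Chi square test" computes; Yates available via flag);
zero-variance t tests follow the convention p = 1 for equal means.  These
statistics are implemented from their closed forms so that standard
library routines can serve as independent cross-checks in the test suite.

## Synthetic data

`simulate_beating_ventricle` emulates the measurement model: a bright
elliptical lumen (default intensities 1000/300/50 counts for
lumen/wall/background) inside a 4 um wall ring, contracting between
end-diastolic semi-axes 50 x 30 um and end-systolic 40 x 21 um (EF 0.608
under the literal volume formula, %FS 30 - mid-range for a healthy
~60 hpf embryo) with a 500 ms period (120 bpm) and a systole fraction of
0.4.  The contraction profile is a C¹ raised cosine in each phase, chosen
so the true volume curve and its derivative have closed forms for rate
parameters.  Edges are rendered with 4x supersampling (sub-pixel
dimension recovery needs anti-aliased edges), then Gaussian blur
(default sigma 1 px) and additive Gaussian noise are applied in that
order, keeping the noiseless limit exactly the blurred geometry.  Not
modelled: optical PSFs beyond Gaussian blur, the atrium and valves,
red-blood-cell speckle, photobleaching, and out-of-plane motion - so
passing recovery tests demonstrates correctness of the measurement chain
on in-plane elliptical geometry, not robustness to every artefact of live
imaging.

`simulate_morphant_cohort` draws per-embryo FI log-normally
(median ~4 arbitrary units, matching the 2-8 range used for binning),
sets true expression to `exp(-k FI)` with k = 0.15 (about 50 % knockdown
at FI 4.6), multiplies log-normal measurement noise (sigma = 0.15), and
classifies phenotype by thresholding true expression (below 0.3 -> no
cardiac output, 0.3-0.6 -> congestion, else none).  Twenty low-FI
controls are appended so control normalisation is always defined.

## Problem sizes and determinism

Validation runs use 128 x 128 px videos of about six cycles at 20 fps
(60-80 frames), five beat geometries plus three noisy replicates at
signal-to-noise 5, and 100 cohorts of n = 300 for the dose-response
check - sizes at which every recovery property is stable while a full
validation pass completes in well under a minute.  All stochastic steps
flow through explicit integer seeds; identical seeds give bit-identical
videos and cohorts.

## Known limitations

- Automatic segmentation assumes a single bright lumen; a bright atrium
  touching the ventricle would merge into one component.
- The half-maximum edge definition carries a small outward bias
  (~0.5 px per edge) under heavy blur, inflating absolute dimensions
  while largely cancelling in EF and %FS.
- The Fourier model assumes strict beat-to-beat periodicity; arrhythmic
  recordings violate the model class, and the residual RMS of the fit is
  the diagnostic to watch.
- The per-frame prolate model treats the imaged section as containing the
  true long and short axes; out-of-plane tilt biases absolute volumes.
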