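# Methods

`magnetokinetics` characterizes magnetotactic bacteria (MTB) from
time-lapse microscopy: per-cell swimming speed, effective radius, and
magnetic moment, and from those the decomposition of a heterogeneous
sample into populations. This note records the models, the numerical
choices, and what the synthetic validation does and does not show.

## The Bean model and U-turn magnetometry

A cell is treated as a self-propelled magnetic dipole: it swims at
constant speed `v` along its body axis while the magnetic torque relaxes
the body axis toward the applied field **B** against rotational viscous
drag,

    alpha dphi/dt = -m B sin(phi),        dx/dt = v (cos th, sin th),

with `phi` the angle between body axis and field, `m` the cell's
magnetic moment and `alpha` the rotational drag coefficient. The heading
equation has the closed form `tan(phi/2) = tan(phi0/2) exp(-t/tau)` with
`tau = alpha/(m B)`; the simulator's RK4 integration is cross-checked
against it in the tests.

When the field reverses, the cell traces a U-turn. In a frame whose +y
axis is the old field direction the turn follows

    y = -(L/pi) ln sec(pi x / L),

and its asymptotic width is `L = pi v alpha / (m B)`, so a fitted width
yields the moment `m = pi alpha v / (B L)`.

**Drag conventions.** The default drag is `alpha = 8 pi^2 eta R^3`
(`drag_convention="paper"`), the form the U-turn calibration was
published with; the classic rigid-sphere value `8 pi eta R^3`
(`"sphere"`) is selectable. The two differ by a factor of pi, which
propagates linearly into `m`. `R` is the effective radius — the radius
of the circle with the detected cell's footprint area — averaged along
the trajectory. Defaults: viscosity `eta = 0.90e-3 Pa·s`, field
`B = 2.55e-4 T`.

**Units.** µm, µm/s, s, tesla at every API surface; SI only inside the
formulas, converted in `units.py`. Pixel coordinates are image-convention
(origin top-left, y down); metric coordinates are mathematically oriented,
with the y-flip applied exactly once in `units.px_to_um`.

## Simulator

Fixed-step RK4 on the joint (heading, position) system at one tenth of
the sampling interval by default. At a reversal the heading is nudged by
1e-3 rad: exact anti-alignment with the new field is an unstable
equilibrium with zero torque, and real cells are never exactly aligned.
Optional rotational diffusion (rad²/s) enters as white noise between
deterministic substeps. Non-magnetic cells (`m = 0`) swim straight and
receive no nudge.

## U-turn analysis

* **Segmentation.** One candidate per reversal, spanning from the
  reversal to the earlier of the next reversal and the heading settling
  within 5° of the new field direction. Candidates with fewer than 10
  points or a net heading change below 90° are discarded — a
  non-magnetic cell therefore produces no candidates and is excluded
  with the reason `"non-magnetic or unfit"`.
* **Canonical frame.** The approach asymptote of the Bean turn is the
  old *field* direction (the `phi -> pi` limit of the integral curve),
  not the cell's instantaneous pre-reversal heading: a cell that has not
  fully settled is a few degrees off, and using its measured heading
  biases the fitted widths by several percent. With a known protocol the
  rotation therefore maps the old field axis to +y; without a protocol
  the measured pre-reversal heading is the fallback. The apex (maximal
  y) is translated to the origin; the residual offset of the sampled
  apex is absorbed by the fit's free offsets.
* **Width fit.** Nonlinear least squares over (L, x-offset, y-offset)
  with the observed x-extent as the initial width. Residuals are scaled
  by `1/sqrt(1 + y'(x)^2)`: the legs of the curve are near-vertical and
  raw vertical residuals would amplify any lateral offset by the slope
  (~50 near the asymptotes), which both biases `L` and traps the
  optimizer. Beyond the asymptotes the model continues linearly (C1) so
  the optimizer keeps a gradient. Rejection rules: normalized RMS
  residual > 0.05; fitted width exceeding 1.2x the observed x-extent
  (the points then only cover the apex of some wider curve — an
  incomplete turn, or a circular arc); optionally a field-of-view bound.
  All thresholds sit in `UTurnParams`.
* **Moment.** Per turn, `m = pi alpha v_segment / (B L)` with the
  segment's own mean speed; the track moment is the mean (median by
  config) over eligible turns.

Noise-free recovery over the grid `m in [1e-16, 1e-14] A·m²`,
`v in [5, 50] µm/s`, `R in [0.3, 1.2] µm` is better than 2% (typically
0.2%); with 0.1 µm position noise and rotational diffusion the median
error stays below 10%.

**Protocol-free reversal detection** locates turns via sign flips of the
heading along the dominant swimming axis (axial circular mean, refined on
the settled subset) and walks each flip back to the onset of the
exponential heading take-off. The onset is only observable once the
deviation `eps * exp(t/tau)` clears the settled-heading floor, with `eps`
the unknown post-reversal misalignment, so detected starts lag the true
reversals by a few frames; segment ends agree with the protocol-based
ones. Use the protocol whenever it is known.

## Detection

Stages, each swappable via `DetectionParams`:

1. **Illumination flattening** — least-squares plane removal (exact for
   linear ramps, immune to blur edge artifacts) followed by heavy
   Gaussian-blur background subtraction (rolling-ball optional); output
   clipped at 0.
2. **Denoising** — 3x3 median by default (bilateral optional). Repeated
   medians keep eroding few-pixel peaks slowly; the flat-region response
   is exactly idempotent.
3. **Segmentation** — optional contrast boost (gamma / CLAHE), then a
   global threshold and connected components. The default threshold is
   `median + 8 * 1.4826 * MAD`: the robust scale ignores the bright cells
   themselves, so the false-positive rate does not depend on how many
   cells the frame contains (a frame-std threshold becomes permissive on
   sparse scenes). Otsu is available for dense, high-contrast scenes.
4. **Area** — the footprint above half of the component's peak,
   evaluated in the continuous form `ln 2 * flux / peak` to avoid pixel
   quantization (`area_mode="pixel_count"` restores the raw component
   size). The half-max footprint is threshold-independent; on the
   synthetic spots it is unbiased within a few percent. Centroids are
   intensity-weighted.
5. **Stack processing** — optional sliding temporal-median subtraction
   (window 51 frames) removes stuck cells and static debris before
   per-frame detection.

## Tracking

A gated global-nearest-neighbour tracker: constant-velocity prediction
from the last three steps, candidate pairs inside
`v_max * dt + slack`, globally optimal Hungarian assignment on distance
(optionally + an area-similarity term), unmatched detections seed new
tracks, tracks unmatched for more than `max_gap = 2` frames close, and
tracks shorter than 10 points are dropped. This deliberately replaces a
full offline multiple-hypothesis tracker: at the cell densities the
physics needs (tens of cells per frame), gated GNN already reaches
association accuracy >= 0.95, and the `Track` contract and CSV header are
identical, so externally produced trajectories can be imported unchanged.

## Velocimetry

Per-step speeds by central differences over the frame timestamps (noise-
robust; a track of n points yields n-2 speeds). The joint
(radius, log10 speed) statistics use per-step instances — not per-track
means — paired with the track-average radius; this mirrors analyses
whose sample sizes (~75,000 instances) far exceed any plausible track
count. Histograms use Freedman–Diaconis binning (`2 IQR n^{-1/3}`,
Sturges fallback at zero IQR) and are normalized to relative frequency.
Speeds below 7 µm/s are labelled passive — a label only, never a filter.
The field-compliance filter (off by default) keeps tracks whose net
displacement lies within a tolerance cone of the expected swimming
direction; for isotropic tracks the kept fraction is 2*tol/360°.

## Population decomposition

* **Density surface.** Product Epanechnikov kernel with per-axis
  Sheather–Jones (solve-the-equation) bandwidths. The SJ selector is
  implemented in-package with the standard binned pairwise sums
  (nb = 1000) and is cross-checked in the tests against R's
  `bw.SJ(method="ste")`; the Gaussian-kernel bandwidth is converted to
  the Epanechnikov half-support by the canonical-kernel ratio 2.2138.
* **Mixture fit.** Sums of scaled bivariate Gaussians
  `a exp(-q/2)` with full symmetric covariance
  `[[s1^2, rho s1 s2], [rho s1 s2, s2^2]]` are least-squares fitted to
  the KDE surface by differential evolution (vectorized objective,
  seeded, L-BFGS-B polish). Sweeps run n ascending and seed a quarter of
  each population with the best (n-1)-fit plus a component at the
  residual peak — without this greedy warm start the optimizer
  under-converges at higher n and the RSS is not even monotone in n.
  An amplitude-parameterized surface fit (rather than maximum
  likelihood on the raw points) is the primary mode because the
  amplitude `a` is part of the published component parameterization;
  negative correlations are allowed.
* **Model selection.** `AIC = N ln(RSS/N) + 2k` over the N grid cells
  with k = 6n parameters, ties broken toward the smallest n within
  ΔAIC < 2. Because neighbouring grid-cell residuals are correlated
  (the KDE smooths sampling noise over the bandwidth), the raw AIC
  minimum tends to add one or two near-zero-amplitude components; the
  scientifically reported quantity is therefore the number of
  *significant* components — those holding at least 5% (configurable) of
  the reconstructed PDF volume `a 2 pi s1 s2 sqrt(1-rho^2)`. On
  single-population synthetic data the significant count is 1 even when
  the raw AIC minimum is not.
* **Critical radius.** Weighted least squares of moment on radius with
  weights `1/sigma_m^2`; `r_c = -b0/b1` with a delta-method standard
  error. A non-positive slope flags `r_c` undefined.
* **Uncertainty envelope.** For 250 evenly spaced directions, the
  q-quantile of the centered projections defines a half-plane; the
  envelope is their intersection (scipy HalfspaceIntersection),
  simplified by Douglas–Peucker and buffered outward by the tolerance so
  simplification never cuts inside the exact region. For an isotropic
  standard normal at q = 0.95 the envelope is a circle of radius 1.645.
  Note the *joint* mass inside is lower than q (each projection is
  bounded at q separately).
* **(r, v, m) clustering.** scikit-learn's variational Bayesian Gaussian
  mixture with a Dirichlet-process weight prior, on internally
  standardized features; clusters with posterior weight > 1% count as
  effective.

## Synthetic data: what it emulates, what it does not

The generators draw cells from bivariate Gaussian mixtures in
(log10 speed, radius) space — the reference parameterizations are the
published population tables for the Ogre River sample (day-1 and day-2
velocimetry, and the moment/radius populations; component weights were
not published, so equal weights are the default) — assign moments either
per component or by the size law `m = b1 (R - r_c)` clipped at zero with
`r_c = 0.57 µm`, swim them through the Bean simulator, and render
Gaussian spots with `sigma = R / sqrt(2 ln 2)` per pixel scale (chosen so
the spot's half-max footprint equals the cell's equal-area disk), linear
illumination gradients, Poisson/read noise, and motionless decoys.

Passing tests therefore demonstrate that the *algorithms* recover known
ground truth under this model. Real data differ in ways the model omits:
non-spot cell shapes (rods, spirilla, aggregates), defocus and
3D motion, flagellar wobble, drift and refocusing, and cell-cell
occlusion. The published count of 846 eligible tracks is not
reproducible here — it depends on the archived raw movies and on
unpublished filter constants — and is not a target of the test suite.

## Problem sizes

Mixture validation uses 75,000-instance samples (the published sample
size) on a 56x56 density grid, differential evolution at population
8 x dim and <= 150 generations with polish — sizes chosen so a full sweep
over n = 1..6 completes in about a minute while recovering component
means to ~0.02 of their generating values. The rendered tracking scenes
use 15–20 cells on 256² px at SNR ~ 7 and ~40 frames; the end-to-end
pipeline test uses four cells on 400² px over 3.5 s at 50 fps. Moment
recovery grids simulate each cell with `dt = min(half/40, tau/2)` so
every turn is resolved by >= 25 samples.

## Known limitations

* 2D only: out-of-plane swimming shortens apparent tracks and biases
  speeds low; no correction is attempted.
* The drag model is a sphere equivalent; strongly elongated cells have
  larger rotational drag than their effective radius suggests, biasing
  moments low by the shape factor.
* U-turn eligibility thresholds (residual <= 0.05, >= 10 points,
  width/extent <= 1.2) are defensible defaults, not calibrated to any
  particular instrument.
* The protocol-free reversal detector lags the true reversal by a few
  frames (see above); prefer the protocol path.
* Mixture decomposition inherits KDE bandwidth leakage: fitted sigmas are
  inflated by the kernel variance (h²/5 per axis for Epanechnikov) —
  negligible at n = 75,000, visible for small samples.
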