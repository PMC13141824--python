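# magnetokinetics

Image-based physical characterization of magnetotactic bacteria (MTB):
from time-lapse microscopy movies (or synthetic stand-ins with known
ground truth) to per-cell swimming speed, effective radius and magnetic
moment, and onward to the decomposition of a heterogeneous environmental
sample into cell populations.

MTB biomineralize chains of magnetic nanocrystals that give each cell a
permanent magnetic moment *m*, so an external field steers them. The
package is written for microbiologists and biophysicists who want to
characterize such cells — most of which cannot be cultured — directly
from microscope recordings.

## What it computes

**U-turn magnetometry (Bean model).** A cell is a self-propelled dipole:
it swims at constant speed *v* while magnetic torque relaxes its body
axis toward the field **B** against rotational drag
α = 8π²ηR³ (sphere-equivalent, R the effective radius). Reversing the
field forces a U-turn along

&nbsp;&nbsp;&nbsp;&nbsp;y = −(L/π) · ln sec(πx/L),

whose asymptotic width L = πvα/(mB) encodes the moment:
**m = παv/(BL)**. The package segments tracks recorded under a
square-wave field into U-turns, fits L to each, and reports per-track
moments with eligibility flags.

**Velocimetry.** Per-step speeds from reconstructed tracks under a
static guiding field; relative-frequency histograms of
(radius, log₁₀ speed) with Freedman–Diaconis binning.

**Population identification.** A smooth density surface (Epanechnikov
kernel, Sheather–Jones bandwidths) is decomposed into scaled bivariate
Gaussians G(µ₁, µ₂, σ₁, σ₂, ρ, a) by differential evolution; the
component count is selected by the Akaike information criterion and
components are ranked by their share of the PDF volume. Companion
tools: an error-weighted linear model for the critical radius r_c below
which cells carry no measurable moment, q-quantile directional envelopes
of the m(R) scatter, and variational Gaussian-mixture clustering in
(r, v, m).

**Upstream of all that:** cell detection in TIFF stacks (background
flattening, denoising, robust thresholding) and gated nearest-neighbour
tracking, plus a synthetic-data module that generates Bean-model tracks
and rendered movies with full ground truth for validation.

## Worked example

```bash
python examples/01_uturn_magnetometry.py
```

```
true moment      : 1.500e-15 A·m²
estimated moment : 1.499e-15 A·m² (from 3 U-turns)
fitted widths    : [6.006 6.006 6.006] µm
relative error   : 0.07%
```

A cell with the sample's most probable moment (1.5·10⁻¹⁵ A·m²),
swimming at 30 µm/s under an alternating 0.255 mT field, traces turns
6 µm wide; the three per-turn widths agree, and the recovered moment is
within 0.1% of the truth.

```bash
python examples/03_population_decomposition.py
```

```
significant populations: 4
fitted components (mu1 = log10 speed, mu2 = radius µm):
  mu1= 0.980  mu2= 0.405  s1=0.393 s2=0.083  rho=-0.37  share=28.0%  [significant]
  mu1= 1.355  mu2= 0.539  s1=0.237 s2=0.025  rho=+0.29  share=25.3%  [significant]
  mu1= 1.428  mu2= 0.692  s1=0.176 s2=0.123  rho=-0.03  share=24.4%  [significant]
  mu1= 0.806  mu2= 0.532  s1=0.261 s2=0.166  rho=+0.52  share=21.9%  [significant]
  mu1= 1.003  mu2= 0.448  s1=0.456 s2=0.019  rho=+0.01  share= 0.5%  [below 5% volume share]
```

Drawn from the four day-1 populations of the Ogre River sample, the
sweep finds exactly four significant components whose means land on the
generating rows; a fifth, near-zero-amplitude component is correctly
flagged as insignificant. The other examples cover the movie →
detection → tracking chain (`02`) and the critical radius + envelope
(`04`).

A thin CLI wraps the same calls:
`magnetokinetics simulate|render|detect|track|velocimetry|moment|populations|run`.

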