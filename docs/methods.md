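# Methods

This note documents the models, measurement procedure, defaults and
numerical choices behind `cortigrad`, and what the synthetic-data tests do
and do not demonstrate about real microscope data.

## Coordinate system

All axial positions are reported in % egg length (%EL): the normalized
projection of a point onto the fitted major axis, 0 at the anterior pole and
100 at the posterior pole. Arc length along the cortex is *not* used as the
reporting coordinate (positions of content quantiles and stripe peaks are
conventionally axial); the dorsal-cortex path does carry its own arc
geometry for disc orientation.

## Synthetic embryo generator

One embryo plane is a rotated ellipse (default semi-axes 250 × 100 px, the
~2.5:1 aspect of a *Drosophila* egg) on a darker slide background. The truth
gradient — uniform, exponential (default amplitude 150 grey levels, decay
length 20 %EL), step, or tabulated — is painted along %EL on one of four
regions:

- `none`: a constant-thickness cortical shell (periplasm), default 8% of the
  semi-minor axis (8 px), measured as Euclidean depth from the embryo
  surface. A constant-thickness shell (rather than a scaled inner ellipse)
  keeps the painted cortex consistent with how the cortical fraction is
  later measured, and matches the morphology of the periplasm, which does
  not thicken at the poles.
- `broad_front`: the whole interior (the SDD-like spread).
- `streak`: a thin axial band (half-width 15% of the semi-minor axis), the
  interior mRNA route of unfertilized eggs.
- `energid_accumulation`: shell plus bright interior nuclei.

Nuclei are stamped as signal-free discs by default (nuclear exclusion before
import) or as local accumulations (`bright`, automatic in energid mode).
Rendering applies Poisson shot noise scaled by `photon_scale` (expected
photons at unit intensity; `inf` disables shot noise), adds a uniform
in-mask autofluorescence baseline (default 12 grey levels) and an
out-of-mask background (default 8), adds Gaussian read noise (SD 1.5), then
clips and floor-quantizes to 8 bits. With the no-saturation flag (default
on, emulating gain adjusted to avoid saturating peak intensities) a
requested noiseless peak at or above the top grey level is refused, and the
noisy image is capped one grey level below the top so the histogram maximum
never reaches it.

The autofluorescence baseline exists so that threshold segmentation sees the
whole embryo even where the gradient has decayed to nothing; the ground
truth record stores the gradient painting only, so truth-based oracles are
unaffected. Signal-to-noise, pixel dimensions and shell thickness of real
recordings are unknown — all of these are configurable, and the defaults are
plausible stand-ins, not measurements.

Stacks are parallel sections of the ellipsoid (a, b, b): a plane offset z
from the midplane is the midsagittal ellipse scaled by `sqrt(1 − (z/b)²)`.
One master seed fans out to deterministic per-plane child seeds; the central
plane reuses the master seed so it is bit-identical to the single-plane
render. Identical spec + seed gives bit-identical images.

## Forward models

Both models run on a regular grid masked to the embryo ellipse (default
500 × 200 µm at 5 µm spacing for 2D, or a 1D line). The per-cell
permissivity factor is 1 in the cortical shell and `yolk_permissivity` in
the interior; diffusive face conductances use the harmonic mean of the two
adjacent cells, so a zero-permissivity neighbour blocks the face exactly and
cortical confinement is exact rather than approximate.

**SDD** integrates `∂C/∂t = ∇·(perm·D ∇C) − ωC` with a constant-flux source
at the anterior cortical tip (first 2 %EL of the shell) and no-flux
boundaries, via an explicit 5-point scheme. The default D = 4 µm²/s is in
the range of classical cytoplasmic estimates for Bcd-scale proteins; ω
defaults to 5 × 10⁻⁴ s⁻¹. Time steps are chosen automatically at 90% of the
stability bound `dx²/(2·ndim·D)` (and `1/ω`); an explicit `dt` above the
bound is refused with the suggested value.

**ARTS** advects mRNA along a 1D transport path — the dorsal cortical
midline, or an interior axial streak — by first-order upwind at `v_mrna`
(default 0.05 µm/s), with optional anchoring until a release time and
degradation `ω_mRNA`. Protein is produced per path cell at `k_translate`
times the mRNA present one translation lag earlier (default 120 s; de novo
synthesis takes about two minutes), deposited into the 2D grid, diffuses
weakly (`D_protein`, default 0.5 µm²/s) on the permissivity mask, and decays
at `ω_protein`. A synthesis stop time supports protein-stability regimes.
The upwind scheme is monotone; both fields stay non-negative at any
admissible step. No published rate constants exist for either model in this
setting, so all defaults are order-of-magnitude choices exposed in the
parameter dataclasses and the run config.

**Condition presets** encode the drug/hypoxia regimes phenomenologically:
`untreated`/`hypoxia` close the yolk (permissivity 0); `vinblastine` opens
it fully (isotropic, SDD-like broad front); `colchicine_colcemid` opens it
partially with energid accumulation in the rendered images; `taxol` changes
nothing; `latrunculin_b` sets cortical transport to zero and triples protein
degradation; `phalloidin` keeps movement mostly cortical with a small
interior leak; `unfertilized` routes the mRNA down the interior streak.
Applying a preset is a pure function on the parameter dataclasses. The
interior mRNA barrier seen late in unfertilized eggs is not modeled (the
streak simply ends at the path's posterior end); an explicit trap term for
energids is exposed as a knob defaulting to 0 and is currently inert in the
dynamics.

## Measurement pipeline

- **Plane selection**: the midsagittal section is the plane with the largest
  segmented area (ties to the lower index). Maximum total signal is a
  plausible alternative criterion; area was chosen because it is monotone in
  distance from the midplane for an ellipsoid regardless of gradient shape.
- **Segmentation**: three-class Otsu (lowest threshold) → largest connected
  component → hole filling → moment-based ellipse fit. The lowest of the
  multi-Otsu thresholds separates slide from embryo even though the embryo
  itself spans dim yolk to bright anterior cortex. Masks with aspect ratio
  < 1.2 are refused (the A–P axis would be undefined). Poles are the
  intersections of the major axis with the mask boundary; the anterior pole
  is the one whose flanking 10 %EL region is brighter, which makes extracted
  profiles invariant to horizontal flips.
- **Dorsal path**: an ellipse with the fitted semi-major axis and the minor
  semi-axis shrunk by half the shell width — it touches both poles, so %EL
  spans exactly 0–100, and sits mid-shell at the dorsal apex.
- **Disc sampling**: elliptical discs oriented along the local path tangent,
  default semi-axis 2.5 %EL along the path, 4% of the semi-minor axis across
  it, stepped by 1.25 %EL (50% overlap), clipped to the embryo mask. The
  modal out-of-mask grey level is subtracted by default, flooring at zero.
  Disc dimensions are configurable; no published values exist.
- **Batch averaging**: profiles recorded under identical gain are resampled
  to a common grid and averaged without per-embryo rescaling; a `rescale`
  flag normalizes each to unit integral first (with a warning) for
  mixed-session batches.
- **Percent-of-total**: each sample's fraction is its trapezoid weight times
  its value over the trapezoid integral; fractions sum to 1.
- **Color conversion**: linear map of [0, scale_max] onto the full 0–255
  LUT, clipping above — scale_max 255 for full range, 85 for the one-third
  scale used to compare a threefold-dosage pair.
- **Dosage ratio**: ratio of in-mask totals after subtracting the *mean*
  out-of-mask level times the in-mask area. The mean (not the mode) makes
  the floor-quantization and read-noise biases cancel between the two
  embryos; the mode has ±0.5 grey-level granularity that would bias totals
  by several percent at 8 bits.

## Gradient statistics

- **Content quantile** `x_q`: the cumulative curve is the trapezoid integral
  of the piecewise-linear profile; within the crossing segment the
  cumulative is quadratic and is inverted exactly (ties to the smallest
  position). Exact inversion rather than chord interpolation keeps the
  statistic consistent with any fine-grid refinement to machine precision,
  which matters for profiles with sharp features. The quantile is scale
  invariant and is computed on the dorsal-cortex profile — the measured
  object — not on whole-embryo mass; with mean-profile versus per-embryo
  averaging both available, the default computes it from the batch mean
  profile.
- **Exponential fit**: offset seeded from the posterior 10% of the range,
  decay length from log-linear regression, refined by nonlinear least
  squares; profiles without dynamic range are flagged flat (λ = ∞) rather
  than fitted.
- **Front position**: 3-sample moving average, reference level = mean over
  the anterior 20 %EL, front = most posterior sample above
  `threshold_frac` (default 0.05) times the reference, 100 if never below.
- **Cortical fraction**: in-shell share of in-mask signal, shell measured by
  Euclidean depth ≤ 8% of the semi-minor axis; background subtracted
  without per-pixel flooring so noise in signal-free regions cancels instead
  of accumulating. Pass a known autofluorescence level as `background` to
  exclude it.
- **Stripe detection**: prominence-based peaks on a ≤ 1 %EL grid with
  parabolic sub-sample refinement; the top `expected_count` by prominence is
  kept, fewer yields a partial result with a warning.

## Problem sizes and tolerances

Default test and acceptance problem sizes were chosen to keep every check
sharp on a single CPU: 260 × 560 px images, 100 × 40-cell simulation grids,
20-seed Monte-Carlo batches, simulated intervals of 20–60 min of embryo
time. At these sizes the 1D steady-state length constant is recovered within
2%, noiseless end-to-end profile recovery achieves r ≥ 0.995 with ≤ 5%
relative RMS, quantile inversion agrees with a 10⁵-point refinement within
0.05 %EL, and stripe centers are recovered within 0.5 %EL at photon-limited
SNR ≥ 10. The cortical shell on the coarse simulation grid is only 1–3 cells
deep, so axial-sum and shell-mean profile exports of the same cortical field
agree in normalized shape to about 7% RMS rather than exactly — a
discretization artifact of the thin shell, not of the transport scheme.

## Limitations

The generator emulates geometry, gradient shape, shell confinement, nuclei
and detector statistics of midsagittal recordings; it does not model optics
(no point-spread function), multi-channel crosstalk, fixation artifacts,
embryo-to-embryo shape variation beyond the ellipse parameters, or staged
nuclear cycles. Passing recovery tests on synthetic data therefore validates
the measurement arithmetic and its geometric conventions, not the biology of
any particular recording. The simulators are deterministic bulk models:
single-molecule noise, nuclear import/export kinetics and parameter fits to
real images are out of scope, and the preset factors are qualitative
encodings of observed phenotypes, not measured rates.
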