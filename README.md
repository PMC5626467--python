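# cortigrad

Quantification of cortical morphogen gradients in syncytial embryos, plus
forward simulators for the two competing hypotheses of how such gradients
form.

## The problem

The anterior–posterior axis of the early *Drosophila* embryo is patterned by
the Bicoid (Bcd) protein gradient. Two models compete to explain its
formation:

- **SDD** (synthesis–diffusion–degradation): protein is translated from mRNA
  anchored at the anterior tip, diffuses freely, and decays uniformly. On a
  long 1D domain the steady state is exponential,
  `C(x) ∝ exp(−x/λ)` with `λ = sqrt(D/ω)`, and transient spreading moves
  posterior **in a broad front through the whole embryo**.
- **ARTS** (active RNA transport + synthesis): the *bcd* mRNA itself is
  transported along cortical microtubules to form an mRNA gradient that
  templates local protein synthesis; the protein then barely moves, and the
  signal stays confined to the **thin cortical shell** (periplasm), with the
  interior yolk acting as a non-permissive territory.

Distinguishing the two from confocal images requires a reproducible
measurement pipeline: pick the midsagittal section of a z-stack, segment the
embryo, fit its ellipse, locate the anterior pole, slide overlapping
elliptical discs along the dorsal cortex to read out intensity versus
% egg length (%EL, 0 = anterior pole), convert profiles to
percent-of-total form, and summarize each gradient by its **content
quantile** `x_q` — the %EL position containing a fraction `q` (default 0.8)
of the profile mass — together with exponential length constants, movement
fronts, the cortical/interior signal partition, and pair-rule stripe-peak
positions.

`cortigrad` implements that pipeline, the two forward models (finite
differences on the embryo ellipse, with named drug/hypoxia condition presets
such as `hypoxia`, `vinblastine`, `latrunculin_b`, `unfertilized`), and a
synthetic confocal-image generator with per-pixel ground truth (Poisson shot
noise, read noise, 8-bit quantization without saturation) so the whole chain
is testable without microscope data. It is aimed at quantitative
developmental biologists and modelers who want gradient statistics that are
auditable end to end.

## Worked example

```python
from cortigrad import (SyntheticSpec, generate_stack, select_midsagittal,
                       segment_embryo, trace_dorsal_cortex, sample_profile,
                       to_percent_of_total)
from cortigrad.stats import quantile_position, fit_exponential

spec = SyntheticSpec(rng_seed=7)            # exponential cortical gradient, λ = 20 %EL
stack, _ = generate_stack(spec, n_planes=7) # confocal-style z-stack
idx = select_midsagittal(stack)             # largest cross-section
plane = stack[idx]
geom = segment_embryo(plane)                # ellipse fit + pole assignment
profile = sample_profile(plane, geom, trace_dorsal_cortex(geom))
norm = to_percent_of_total(profile)
print(f"midsagittal plane: {idx}")
print(f"egg length: {geom.egg_length_px:.0f} px")
print(f"x_0.8 = {quantile_position(norm, 0.8):.1f} %EL")
print(f"lambda = {fit_exponential(profile).lambda_pct_el:.1f} %EL")
```

prints

```
midsagittal plane: 3
egg length: 501 px
x_0.8 = 49.9 %EL
lambda = 20.3 %EL
```

The central plane of the 7-plane stack is correctly selected; the fitted egg
length matches the generating ellipse (2 × 250 px); the fitted decay length
recovers the painted truth (20 %EL) to 1.5%. `x_0.8 = 49.9 %EL` says 80% of
the measured profile mass lies anterior of midlength — note this includes
the uniform autofluorescence baseline the generator paints, which is why it
sits posterior of the value for the pure gradient. Passing the in-mask modal
grey level as the `background` of `stats.cortical_fraction` removes that
baseline and reports a cortical fraction of 1.00 for this cortex-confined
embryo, versus < 0.5 for a `broad_front` (SDD-like) rendering.

The same stages run from the shell:

```sh
cortigrad run --seed 7 --out demo_out            # synthesize → extract → quantify
cortigrad simulate --model sdd --preset vinblastine --out sim_out
cortigrad colormap demo_out/embryo_000.tif --scale-max 85 --out third_scale.png
```

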