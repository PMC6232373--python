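# neuroscreen

Image-based screening of neuronal differentiation and neurite alignment on
nanogrooved substrates.

Nanogrooved culture substrates (pattern period *D*, ridge width *L*, both in
nanometres, written `DxxxLyyy`, e.g. `D450L180`) guide the outgrowth of
neurites from differentiated neuron-like cells such as SH-SY5Y. Quantifying
that guidance across dozens of substrate geometries requires an automated,
unbiased readout from large sets of fluorescence micrographs. `neuroscreen`
implements that readout end to end for three-channel epifluorescence images
(nuclear counterstain, F-actin, β-Tubulin III):

1. **Feature detection** — nucleus-seeded watershed segmentation of somata,
   multiscale ridge enhancement + hysteresis + skeletonisation of neurites,
   graph-based tracing that links every neurite tree to its soma and counts
   branches; cells are classed unipolar / bipolar / multipolar by bearing
   1 / 2 / >2 neurites.
2. **Alignment quantification** — the core statistic. On the *neurite-only*
   image (somata and background removed), the 2D Frangi vesselness filter
   assigns every pixel a ridge likelihood

   V = exp(−R_B² / 2β²) · (1 − exp(−S² / 2c²)),  with λ₂ < 0,

   from the σ²-normalised Hessian eigenvalues |λ₁| ≤ |λ₂|
   (R_B = |λ₁|/|λ₂|, S = √(λ₁²+λ₂²)), and the along-ridge orientation from
   the λ₁ eigenvector. The **alignment percentage** is the share of
   supra-threshold pixels whose axial orientation lies within 30° of the
   substrate pattern direction. Under an isotropic neurite distribution
   (flat substrate, reference angle 0°) this converges to 60/180 = **33.3%**.
3. **Cross-checks** — a Fourier-spectrum directionality histogram (binned
   structure orientations from the power spectrum) and a per-neurite chord
   measurement (straight line from neurite start to tip), both with the same
   ±30° rule.
4. **Screening statistics** — Lilliefors normality (Monte-Carlo p-values),
   Kruskal–Wallis with Dunn's post hoc test, Spearman rank correlation,
   median/IQR summaries, and the derived per-image variables (differentiated
   fraction, B/U and M/U polarity ratios, branching fractions, mean neurite
   length).

Because no image dataset is distributed with this method, the package ships
a seeded synthetic-scene generator (`neuroscreen.synthetic`) that renders
sparse SH-SY5Y-like cultures with complete ground truth — soma positions,
neurite polylines, chord angles, arc lengths, branch counts, and the true
aligned fraction — so every stage is testable and calibratable.

## Worked example

```python
import numpy as np
from neuroscreen import (
    SceneSpec, generate_culture_image, analyze_stack,
)

spec = SceneSpec(aligned_fraction=0.8, pattern_angle_deg=15.0)
stack, truth = generate_culture_image(spec, seed=7)
record, qc = analyze_stack(stack, "demo", "D450L180", pattern_angle_deg=15.0)
print(f"cells: {record.n_cells}, differentiated: {record.n_cells_with_neurites}, "
      f"neurites: {record.n_neurites}")
print(f"true aligned fraction: {truth.true_aligned_fraction:.2f}")
print(f"vesselness alignment: {record.alignment_vesselness:.1f}%")
print(f"FFT alignment:        {record.alignment_fft:.1f}%")
print(f"chord alignment:      {record.alignment_chord:.1f}%")
```

prints

```
cells: 8, differentiated: 7, neurites: 11
true aligned fraction: 0.92
vesselness alignment: 87.5%
FFT alignment:        68.0%
chord alignment:      90.9%
```

A scene requested with 80% of orientations drawn from the concentrated
component realised a 0.92 aligned chord fraction over its neurites; the
per-pixel vesselness statistic reports 87.5% of neurite pixels within 30°
of the 15° pattern direction, the per-neurite chord oracle 90.9%, and the
whole-image FFT histogram — which spreads mass over all spatial structure —
a softer 68.0%. All three move together as alignment varies, which is the
behaviour the screening method relies on.

Batch work goes through the CLI (`neuroscreen simulate | angle | screen |
stats`): a manifest CSV maps image files to substrate names, pattern angles
come from a per-substrate reference image (`estimate_pattern_angle`) or a
manual override, and `screen` writes the screening-record table, the Dunn
pairwise table and a plain-text statistics report.

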