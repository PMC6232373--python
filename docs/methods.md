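# Methods

This note documents the models, conventions, parameters and numerical
choices behind `neuroscreen`, and what the synthetic validation batteries
do and do not demonstrate about real micrographs.

## Angle convention

All orientations are *axial* — lines, not vectors — in degrees on the
half-open interval [−90°, 90°), measured counterclockwise from the +x
(column) axis of a row-major image with origin top-left (so +y points
against the row index). The separation of two axial angles is
min_k |a − b + 180k| ∈ [0°, 90°]. Every module (generator, Hessian
orientation, FFT histogram, chord measurement, pattern angle) uses this one
convention; the 90° rotation between a structure and its Fourier spectrum
is applied *inside* the directionality histogram so that all orientation
outputs are directly comparable.

## Vesselness orientation field (`neuroscreen.orientation`)

For each scale σ, the Hessian of the Gaussian-smoothed image is computed
from derivative-of-Gaussian filters and scale-normalised by σ². With
eigenvalues ordered |λ₁| ≤ |λ₂|, the bright-ridge vesselness is
V = exp(−R_B²/2β²)(1 − exp(−S²/2c²)) for λ₂ < 0 and 0 otherwise, where
R_B = |λ₁/λ₂| and S is the Frobenius norm of the Hessian. The per-pixel
response is maximised over scales and the ridge orientation taken from the
λ₁ eigenvector at the maximising scale.

Parameter defaults and rationale:

- **scales σ = {1, 1.5, 2, 3} px** — brackets ridge widths of roughly 2–6
  px FWHM, matching thin neurites imaged at 10× with ~0.65 µm/px.
- **β = 0.5** — the standard blobness sensitivity; an isotropic blob
  (R_B = 1) is suppressed by e^(−2) relative to a perfect ridge.
- **c adaptive, per scale** = half the maximum S observed at that scale.
  Adapting per scale (rather than once per image) is the common convention
  in published 2D implementations and keeps weak large-scale responses
  from being drowned by the strongest fine-scale contrast. A fixed c can
  be passed explicitly.
- **vesselness threshold 0.15** — the support cutoff for the alignment
  statistic; configurable everywhere it is used.
- Orientation is undefined (NaN, excluded from support) where the
  eigensystem is degenerate (λ₁ = λ₂) or V = 0 — no meaningful ridge
  direction exists there.
- The DC level is subtracted before filtering: the truncated derivative
  kernels do not sum exactly to zero, and removing the mean keeps constant
  images exactly flat.
- Bright ridges on dark background are assumed (fluorescence);
  `dark_ridges=True` negates the image.

The **alignment percentage** counts support pixels whose orientation
differs from the pattern angle by *strictly less than* the cutoff
(default 30°). The strict comparison follows the workflow definition
("detected angle relative to the pattern < 30°"); for continuously
distributed orientations the boundary has measure zero. Per-pixel (not
per-segment) weighting is deliberate: every neurite pixel above the
likelihood threshold votes once. An empty support yields an undefined
(NaN-flagged) result, never 0%.

## FFT directionality (`neuroscreen.directionality`)

The image is mean-subtracted, windowed with a 2D Hann window, and the
power spectrum binned by structure orientation (spectral angle + 90°) into
90 bins of 2°. The DC component and a low-frequency disc of radius 3
samples are excluded, as are samples outside the inscribed Nyquist disc —
the corners of a square spectrum sample diagonal orientations more densely
and would bias the histogram. Mass is normalised to 1. The histogram
alignment percentage sums the mass of bins whose centre passes the same
strict ±30° rule.

## Pattern reference (`neuroscreen.patterns`)

`DxxxLyyy` parses to period and ridge width (nm); groove width = D − L and
the ridge-to-period ratio L/D follow. Flat controls carry the conventional
pattern angle 0°. The groove direction of a substrate is estimated from a
reference image of the pattern edge: the modal bin of the directionality
histogram locates the direction coarsely, then a power-weighted axial
circular mean of the spectral samples within two bin widths of the mode,
re-centred once, refines it. The refinement replaces three-point parabolic
interpolation of bin masses, whose accuracy (~1°) is limited by the
angular quantisation of coarse frequency samples; the circular-mean
refinement achieves ≤ 0.5° on the bundled reference-stripe fixtures
(worst case ~0.7° at bin-edge angles). Estimation fails loudly — prompting
manual entry — when the peak bin holds less than 2× the uniform mass
(dominance criterion, a package choice). A manual per-substrate angle
always takes precedence, preserving parity with manual measurement
workflows.

## Feature detection (`neuroscreen.detection`)

All parameters of this stage are explicit `DetectionParams` fields, since
the interactive wizard settings of the commercial tool it replaces are not
public. The defaults were chosen against the bundled synthetic scenes:

- Somata: nuclei channel smoothed (σ 2 px), Otsu threshold, minimum seed
  area 25 px; seeds drive a watershed on the smoothed F-actin channel,
  whose foreground is opened with a 2 px disk to erase thin neurites.
  A foreground/background mean-contrast guard (≥ 2) rejects noise-only
  nuclei channels, which would otherwise Otsu-split into spurious seeds.
- Neurites: vesselness of the tubulin channel (same filter as the
  alignment pathway), soma interiors dilated by 3 px excluded, hysteresis
  thresholds 0.05/0.15 on the vesselness likelihood, components under
  10 px dropped, skeletonised, terminal spurs under 6 px pruned. A 1.5×
  contrast guard rejects signal-free tubulin channels.
- Linking: the skeleton becomes an 8-connected pixel graph (diagonal steps
  √2). Skeleton pixels within the attachment radius (8 px) of a soma form
  contact clusters; a cluster roots a neurite when it contains a skeleton
  endpoint, a junction, or a pixel within 2 px of the soma — a neurite
  merely *passing by* a foreign soma stays degree-2 through its contact
  zone and is not captured. Components touching several somata are
  partitioned by graph distance to the roots (ties to the lower cell id).
  Junctions within 10 px of a root split the tree into separate *primary*
  neurites (sub-trees ≥ 15 px): neurites that emerge side by side from one
  soma merge in the image and would otherwise be counted once. Junctions
  further out count as branches, with adjacent junction pixels collapsed
  so one bifurcation is one branch.
- Length: geodesic length of the root-to-tip path (diagonals √2), plus the
  root-to-soma gap created by the exclusion zone, scaled by the pixel
  size. Polarity follows the neurite count per cell (1 = unipolar,
  2 = bipolar, >2 = multipolar; 0 = none).
- The neurite-only image keeps tubulin intensities on the skeleton dilated
  by 2 px, with soma pixels and background zeroed; it is the sole input of
  both alignment pathways in neurite-only mode.

One numerical subtlety: the *hysteresis monotonicity* property
("raising the threshold pair never increases skeleton length") holds
exactly for the detected support mask, but discrete skeletonisation
wobbles by up to ~2%: thinner masks skeletonise to marginally more jagged
centerlines, and fragmented components escape junction-based spur pruning.
The test suite asserts exact monotonicity of the support and 2%-bounded
monotonicity of the skeleton.

## Statistics (`neuroscreen.stats`)

- **Lilliefors**: KS distance against a normal with estimated mean/sd;
  the p-value comes from 10⁴ Monte-Carlo null replicates with a fixed
  internal seed, avoiding critical-value table dialects. The statistic is
  cross-checked against statsmodels in the tests.
- **Kruskal–Wallis** and **Spearman** are delegated to scipy (tie-corrected)
  behind the module surface, and verified against brute-force rank
  enumeration oracles to 1e−9 in the tests. An all-tied pooled sample
  returns H = 0, p = 1.
- **Dunn's post hoc** is implemented directly (pooled tie-corrected ranks,
  z per pair); the multiplicity adjustment defaults to Bonferroni over all
  pairs (configurable: holm / none), since the original description names
  the test without a correction family. Adjusted p ≥ raw p always.
- **Spearman CI** (optional) uses the Fisher transform at the 99% level,
  matching the convention of calling correlations significant at P < 0.01.
- Quantiles use linear interpolation (numpy default), asserted against a
  sort-and-interpolate oracle.
- Derived variables: undefined ratios (e.g. B/U with no unipolar cells)
  propagate as missing and are dropped per group with QC counts; images
  without cells are excluded and logged. Both per-image and per-substrate
  (median-collapsed) aggregation levels are supported, since the unit of
  analysis in such screens is ambiguous between the two.

## Synthetic scenes (`neuroscreen.synthetic`)

The generator emulates sparse differentiated cultures imaged at 10×:
a 384×384 px field at 0.65 µm/px (~250 µm), 8 well-separated somata
(minimum separation 5× the mean soma radius — low-density seeding), soma
radii 6 ± 1 µm, 0–3 neurites per cell with probabilities
(0.15, 0.30, 0.35, 0.20), lengths 45 ± 10 µm, 15% branch probability.
Neurite orientations are drawn from a mixture: with probability
`aligned_fraction` a wrapped normal (sd 5°) around the pattern angle,
otherwise uniform on the axial circle; paths are bounded-turn random walks
(≤ 5°/1.5 px step) so the chord angle tracks the drawn heading. Rendering:
Gaussian blobs for nuclei/somata, constant-width Gaussian-profile ridges
(σ = 1 px) for neurites (attenuated 0.35× in the actin channel), an uneven
planar background (level 8), Poisson shot noise then Gaussian read noise
(sd 2). The pixel size (0.65 µm at 10×) and 16-bit export are declared
defaults — plausible for the emulated microscope class, not calibrated to
any instrument.

`generate_neurite_field` renders *straight* segments whose centres are
placed so every segment lies fully inside the frame; pixel mass per
neurite is then independent of orientation, which matters for the isotropy
calibration. The closed-form mixture expectation used in the recovery
tests is 100·(f·p_c + (1−f)/3) with p_c ≈ 1 at 5° spread.

What passing the synthetic batteries shows: the pipeline recovers known
ground truth (cell counts exactly, mean neurite length within ~10%,
polarity ≥ 90% on the default battery), the per-pixel alignment statistic
is calibrated (33.3% under isotropy, within 7 points of the mixture
expectation across aligned fractions) and the three alignment estimators
rank scenes consistently (pairwise Spearman r > 0.9). What it does not
show: robustness to dense or overlapping cultures, debris and staining
artefacts, uneven illumination beyond a planar gradient, out-of-focus
fields, or real point-spread functions — real micrographs will need
per-dataset tuning of the documented `DetectionParams`.

## Problem sizes in the validation suites

The bundled batteries are sized for routine re-runs on one CPU: the
isotropy calibration uses 50 fields of 100 straight neurites (512×512 px),
parameter recovery 20 default scenes plus 25 neurite fields, cross-method
consistency 30 scenes, and the type-I calibration 2000 Kruskal–Wallis
null simulations; the whole test suite completes in about a minute.

## Known limitations

- Neurites that genuinely terminate on a foreign soma are attached there;
  with dense cultures this inflates that cell's neurite count (and real
  feature-detection software faces the same ambiguity).
- A branch that forks within 10 px of the soma is counted as an extra
  primary neurite by construction; the generator places branches beyond
  one-third of the neurite length, and biological primary-neurite counts
  follow the same convention.
- The vesselness contrast normalisation is per image; signal-free images
  are caught by the contrast guards rather than by the filter itself.
- Pattern-angle estimation assumes a single dominant linear structure in
  the reference image; multi-directional references require the manual
  override.
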