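# Methods

## Problem and scope

A picket-fence (PF) acquisition images ten narrow slits formed by a dynamic
MLC onto the portal imager. QA software measures, per leaf pair and per
slit, the slit *position* and *width* to sub-pixel accuracy and flags
deviations. The same physical image, analyzed with different template
placements, threshold conventions and reference choices, yields different
detection behavior. `pfqa` builds the whole loop — plan, fault injection,
image formation, analysis, scoring — so those behaviors can be quantified
against exact ground truth rather than argued about.

The package models *integrated* acquisitions only: leaf speed and delivery
dynamics are irrelevant because only the time-integrated aperture reaches
the detector. Gantry-rotation (gravity) effects, Monte-Carlo transport,
detector glare/ghosting and absolute dosimetric calibration are out of
scope.

## Coordinate conventions

All plan quantities live in the beam's-eye view at the isocenter plane, in
mm: crossplane `x` along leaf travel (positive toward the bank-A tips),
inplane `y` positive toward leaf pair 1. Leaf pairs tile the inplane extent
symmetrically about the axis with half-open intervals `[low, high)`,
1-based from the positive-y end. Panel scale is handled exclusively by the
imager model through the recorded pixel spacing and SAD/SID.

## Reference plan

Ten slits of 1 mm nominal gap spaced 15 mm. The stated jaw apertures
(X1 = 7.5 cm, X2 = 9.1 cm) are only consistent with the jaw edges sitting
15 mm outside the *outer edges* of the first and last slits, which places
the slit centers at −59.5 … +75.5 mm; this closure
(`x1 + x2 = 135 + 1 + 30 = 166 mm`) is a checked invariant. Two leaf pairs
are excluded behind each Y jaw (Y aperture 36 cm for the M120's 40 cm leaf
bank, 20 cm for the HD120's 22 cm bank). 100 MU, collimator 0°.

## Image formation

The collimated fluence is a weighted sum of axis-aligned rectangles (jaw
box, per-pair slit cells) plus Gaussian ridges on the leaf-pair boundaries
(interleaf leakage). Penumbra is an isotropic Gaussian, applied
*analytically*: a rectangle convolved with a Gaussian separates into
error-function factors, so rendering is exact at any pitch and fast
(≈0.5 s per 1280² frame). Collimator rotation exploits that an isotropic
Gaussian commutes with rotation: the blurred pattern is evaluated at
back-rotated coordinates. Pixels are midpoint samples of the blurred
field; with σ ≫ pitch the midpoint error of the pixel integral is
below 10⁻¹⁰ (Poisson summation), which the blur-conservation test verifies
against exact rectangle arithmetic.

Model parameters (all configurable on `BeamModel`):

| parameter | default | rationale |
| --- | --- | --- |
| `penumbra_sigma` | 0.8 mm | typical 6 MV EPID penumbra; gives ≈2 mm FWHM for a 1 mm slit |
| `oar_coeffs` | (6e−7, 8e−12) | radial off-axis ratio `1 + c2·r² + c4·r⁴`, ≈+2.8% at r = 180 mm — enough horn structure to make baseline widths vary off-axis |
| `leaf_transmission` | 1.5% | Millennium-class leaf transmission |
| `interleaf_leak_amplitude` / `interleaf_sigma` | 0.3% / 0.2 mm | narrow inter-leaf ridges; the mechanism behind field-edge misestimation near jaws |
| `jaw_transmission` | 0.5% | below-leaf background outside the jaws |
| `jaw_y_calibration_error` | 0 mm | common-mode Y-jaw offset: the radiative field moves, the MLC pattern does not |
| `noise_level` | 0.2% | multiplicative Gaussian; integrated images are high-count |

Imager pose errors displace the *sampling grid* (vertical along the beam
axis changes the magnification `(SAD+d)/SAD`; lateral/longitudinal shift
the panel) while the DICOM metadata keep recording nominal geometry — this
is precisely why pose faults are only discoverable through the image.
Images round-trip through DICOM RT-Image (16-bit with rescale slope).

## Slit measurement

Profiles are extracted under each leaf pair from the central 50% of the
pair's row band, averaged, and smoothed with a centered moving average
(3 pixels by default). Slit position and width come from the
threshold-midpoint rule: the two crossings of the profile with a threshold,
located by linear interpolation between samples; position = midpoint,
width = crossing distance. On analytic profiles (trapezoid,
Gaussian-convolved boxcar sampled at 0.05 mm) this matches closed-form
crossings to <10⁻³ mm; on rendered 0.336 mm-pitch images the end-to-end
recovery of injected 0.1–0.5 mm shifts is accurate to ≈0.03 mm.

Thresholds: *local* — `T = bg + f·(peak − bg)` per slit and pair;
*global* — one image-wide `T` keyed to the extreme slit peak. `f = 0.5`
by default; the commercial values are unpublished, so `f` is explicit
configuration. Background is the median of the profile outside all search
windows, between the slits. Search windows are the nominal slit positions
±5 mm (plan-derived for the field-edge template, detected peaks for the
image-center template).

### Template strategies

* `field_edge` — Y-jaw radiative edges at 50% of the in-field signal anchor
  the band layout; bands carry *physical* pair indices; the crossplane
  windows track the detected field laterally. A Y-jaw calibration offset
  therefore shifts the whole template: at about half an HD120 leaf
  (1.25 mm) a pair-30 fault is attributed to pair 30 or 31.
* `image_center` — bands are laid out from the image center assuming all 60
  pairs visible and labelled sequentially from the first signal-bearing
  band. With two pairs hidden behind each Y jaw, physical pair 30 is
  reported as 28. This strategy deliberately never consults the plan; the
  asymmetry is the point, not a bug.

The outermost signal-bearing band at each end is excluded from
measurement: within the jaw penumbra, a tilted jaw edge (collimator
rotation ≥1°) cuts into the band ROI and fakes width/signal changes that
the emulated systems do not exhibit. Template-labeling diagnostics still
use the full signal-bearing set.

### Metric families

*Relative* (field-edge template): per-pair position error vs the same pair
of the reference slit (the 5th) minus the nominal spacing; per-pair width
error vs a stored baseline analysis (nominal gap as a flagged fallback);
per-slit mean/max roll-ups; per-slit background-subtracted signal
integral, computed over a span centered on the *measured* slit so pose
errors do not clip it. A second position detector, the *intra-slit
deviation* (residual of each pair against its slit's own fitted line), is
required by the fault phenomenology: a leaf fault injected on every slit —
including the reference slit — cancels exactly in the inter-slit
comparison, yet such faults are detected by reference-slit systems at the
correct pair while remaining insensitive to collimator rotation; a
line-fit residual has exactly these two properties (the fit absorbs the
tilt, the faulted pair sticks out).

*Absolute* (image-center template): per slit, a line is fitted to
(pair center, position); the picket offset is the fitted position on the
central axis; per-leaf deviation is position minus the picket offset (not
minus the fitted line — so a rigid rotation grows the maximum deviation
with |y·sinθ| instead of being absorbed); pass rate at a 0.3 mm criterion,
median and maximum |deviation| with pair identification, mean spacing of
consecutive picket offsets.

### Width-threshold phenomenology

With the spec'd σ = 0.8 mm penumbra, a fraction-of-peak threshold on a
lightly smoothed profile retains ≈30% of a uniform gap opening in the
measured width (the normalized erf profile is not amplitude-invariant), so
a plain image-wide threshold would *not* be blind to uniform openings.
The image-wide-threshold configuration therefore applies a wide (6 mm)
moving average first. In the wide-window regime the profile is a plateau of
height ∝ slit integral with erf edges at the window boundaries, and at
`f = 0.5` the crossings sit at the plateau edges offset by the slit-profile
*median* — independent of the gap. Uniform openings then change measured
widths by <0.005 mm, while a single opened slit still pulls the shared
threshold up and visibly shrinks every *other* slit's width (−0.21 mm for
a 0.1 mm opening). The per-slit-threshold configuration keeps the narrow
3-pixel smoothing: it under-reports openings (<half the injected value)
but its slit-signal integral tracks them exactly (+10% per 0.1 mm on a
1 mm gap).

## Sensitivity evaluation

Every scenario image is analyzed by all three method presets
(`relative_local`, `relative_global`, `absolute_center`) and compared
cell-by-cell against the same preset's analysis of the reference
acquisition. A metric *departs* when it moves beyond
`max(3 × across-seed std on reference renders, resolution floor)`; the
resolution floors are 0.1 mm for positions and widths (the stated accuracy
of the threshold-midpoint measurement), 0.5% for the slit signal, 0.02 mm
for mean spacing, 1 percentage point for the pass rate and half a band for
template labeling. Pure 3σ floors would both flag physically real but
sub-resolution residuals (e.g. the (1/cosθ − 1)·Δx ≤ 0.05 mm inter-slit
stretch at 2° rotation) and produce ≈0.3% false-positive cells by chance;
the resolution floors give zero false positives over 20 seeded reference
renders, which is a test.

Verdicts: *indicated* needs a departure that localizes the true
slit/pair, a recovered magnitude within 0.1 mm of truth (position faults
only — width magnitudes cannot be related to the injected gap change, so
width faults cap at *sensitive*), and an alerting method family (the
absolute family has no alerting and caps at *sensitive*). Fault families
aggregate over their magnitudes by strongest verdict, matching how a fault
class is reported as a whole. Pose and signal faults are scored as
impacted/not-impacted (any departure vs none).

## Problem sizes and determinism

The full evaluation (110 scenarios × 3 presets plus floor estimation) runs
at the native 1280² panel in ≈1 minute on one CPU; the analysis scripts and
tests use it directly. `ImagerSpec.scaled()` provides coarser panels for
interactive work; note that at half resolution the width measurement
acquires ≈0.1 mm sub-pixel-phase wiggle, which is why quantitative studies
stay at native pitch. Every stochastic step draws from
`numpy.random.default_rng` seeded per scenario from a single master seed;
repeated runs are bit-identical.

## What the generator does and does not emulate

It reproduces the features the analysis methods react to: penumbra,
radial non-flatness (hence off-axis width baselines), transmission and
interleaf structure, magnification and pose hiding, MU scaling and
high-count multiplicative noise. It does not model detector glare,
backscatter asymmetry, leaf-end curvature, tongue-and-groove structure in
the leaf sides, or delivery dynamics. Passing tests therefore demonstrate
properties of the *analysis methods* under a faithful geometric/intensity
model, not detector physics fidelity; on real images the absolute levels
of width baselines and signal integrals will differ, while the relative
phenomenology (blind spots, misidentification mechanisms) is driven by the
analysis geometry and carries over.

## Known limitations

* The 30/31 attribution ambiguity is reproduced at the half-leaf balance
  point of the template shift; the sign of the jaw calibration offset
  decides whether the neighbor is 31 or 29.
* The global-threshold blindness is a property of the wide-smoothing +
  50%-threshold configuration; other fractions re-acquire partial width
  sensitivity (see `analysis/04_width_blindness.py`).
* Injected shift signs are reported as measured; the evaluation compares
  magnitudes because the physical sign convention of a "bank shift" is not
  observable from a single integrated image.
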