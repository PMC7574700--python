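# Methods

`osteoquant` re-implements, as a tested pipeline, the multiscale
characterization workflow used to compare femoral bone quality between a
control group and a diabetic (T2D) group of rats: whole-bone mechanics
from three-point bending, tissue-level mechanics from cyclic
reference-point indentation (cRPI) and nanoindentation, composition from
FTIR and XRD, total fluorescent advanced glycation end products (fAGEs)
from plate assays, structure from voxel morphometry, and the small-cohort
statistics tying them together.  A synthetic-cohort generator forward
models every raw instrument output from latent per-animal parameters, so
each analysis stage can be validated against known ground truth without
any external data.

## Three-point bending

A load–displacement trace (19 mm span, 10 N preload, 10 mm/min, sampled
at 100 Hz) yields:

- **Stiffness** — the slope of the elastic portion.  The "linear portion"
  is identified automatically: among sliding windows between the preload
  and 80% of F_max, the longest one whose RMS residual about its own
  least-squares line stays at the trace's noise floor (estimated robustly
  from median-centered first differences, with an absolute floor of
  10⁻⁴ × the band's top force).  Among near-maximal candidates the
  steepest is taken, because a post-yield plateau can be just as linear
  but is never the elastic response.  A fit with R² ≥ 0.98 must exist or
  the trace is rejected as having no linear region.  A pure R²-threshold
  window was found to creep into the post-yield curvature and bias the
  slope by several percent on curved-hardening traces, which motivated
  the residual-based criterion.
- **Yield point** — 0.2% offset convention: the elastic fit line is
  translated along displacement by `offset_fraction × span` (0.038 mm by
  default; the reference length for the offset is the support span, a
  strain-equivalent convention, configurable) and the first intersection
  with the trace is `(D_yield, F_yield)`.  A trace the offset line never
  crosses is flagged and reported with `PYD = 0`.
- **Fracture** — the last sample before the load drops below 50% of
  F_max, else the final sample.
- **Work-to-failure** — trapezoidal area under the curve from the start
  of the record to fracture, reported in N·mm.  (Work quoted "per mm"
  in some protocol write-ups is treated as the same N·mm quantity.)
- **PYD** = D_fx − D_yield.

The forward model is linear to a proportional limit, then two
tangent-continuous quadratic Bézier arcs: one through the exact offset
yield point, one peaking at `(D_fx, F_max)` with zero end slope, followed
by a sharp terminal drop.  The post-yield tangent at yield is the
geometric mean of the elastic slope and the mean hardening slope, which
keeps both arcs monotone.  The trace's analytic area (triangle plus two
cubic polynomial integrals, exact under 4-point Gauss–Legendre) is the
oracle for the work computation.  Zero-noise roundtrips recover all four
parameters to well under 1%.

## Cyclic reference-point indentation

Ten cycles to a fixed 8 N peak at 2 Hz, several indent sites per bone.
An interleaved record is segmented at the force minima between peaks
(boundary samples shared so every loop closes); a deviating cycle count
produces a warning, not an error.  Per site: ID-1st and TID are the
depths at peak force of the first and last cycle, IDI = TID − ID-1st,
US-1st is the linear-fit slope of the first cycle's unloading branch over
40–95% of peak force (window configurable; the instrument convention is
not standardized), and the per-cycle energy dissipation is the enclosed
loop area by the shoelace formula (orientation-independent; a non-closed
final cycle is integrated to its last sample and flagged).  Avg-ED
averages all ten cycles by default; a flag excludes the first cycle,
since conventions differ.  Sites are averaged unweighted.  The forward
model uses straight loading/unloading branches whose start points are
positioned so each loop's area equals the requested energy exactly, with
the peak-depth schedule `first_depth + (c−1)·creep` — hence IDI, US-1st
and Avg-ED are controlled exactly by construction.

## Nanoindentation (Oliver–Pharr)

Berkovich indents to 1000 μN with 10 s load / hold / unload segments.
The upper unloading branch (40–95% of P_max) is fit with
`P = α(h − h_f)^m` (m bounded to [1, 3]); contact stiffness
`S = dP/dh` at `h_max`; contact depth `h_c = h_max − ε·P_max/S` with
ε = 0.75; ideal-tip area `A = 24.5·h_c²` (no β correction; both
configurable); `H = P_max/A`; `Er = (√π/2)·S/√A`.  Units: μN and nm,
with 1 μN/nm² = 1000 GPa.  The forward model builds the self-consistent
curve (loading `P = P_max(h/h_max)²`, unloading power law with
`h_f = h_max − m·P_max/S`), so inversion is exact to ≤10⁻⁶ relative —
verified as a property over (Er, H) ∈ [1, 100] × [0.05, 5] GPa wherever
the implied residual depth is non-negative.

## FTIR composition

Spectra span 400–1800 cm⁻¹ on a 2 cm⁻¹ grid.  Every analysis window uses
a linear baseline through its endpoint values (the closest deterministic
analogue of interactive baseline correction).  Ratios:

| parameter | definition |
|---|---|
| mineral-to-matrix | area 916–1180 (phosphate ν1ν3) / area 1596–1712 (amide I) |
| carbonate-to-phosphate | area 852–890 (carbonate ν2) / phosphate area |
| crystallinity | baseline-corrected intensity 1030 / 1020 |
| acid phosphate | intensity 1127 / 1096 |
| NE-xLR | amide I sub-band area 1678 / 1692 |
| collagen maturity | amide I sub-band area 1660 / 1692 |

Intensity ratios use heights, as named.  The collagen-maturity
denominator is the fitted 1692 cm⁻¹ sub-band (the conventional "1690"
band is not among the six fitted positions; 1692 is the nearest).

The amide I envelope is deconvolved into six Gaussians at 1610, 1630,
1645, 1660, 1678 and 1692 cm⁻¹ — positions established from
second-derivative spectra, which is also how the fit is initialized:
amplitudes from the magnitudes of local second-derivative minima (for a
Gaussian, |y''| at center = amplitude/σ²), widths starting at 10 cm⁻¹
and bounded to [4, 30], centers bounded to nominal ± 4 cm⁻¹.
Non-convergence triggers one restart from flat amplitudes.  The
generator's sub-bands use σ = 5 cm⁻¹ (FWHM ≈ 11.8 cm⁻¹, within the
range reported for amide I components): at widths much above this the
six-component model becomes practically unidentifiable (near-perfect
fits with badly redistributed areas), so narrower, realistic bands are a
condition for meaningful sub-band areas — a caveat that applies equally
to real spectra.

The generator realizes requested ratio sets exactly: phosphate
sub-components at 960/1020/1030/1096/1127 cm⁻¹ whose amplitudes solve a
small linear system for the target probe intensities, scaled against the
amide envelope for the target mineral-to-matrix area ratio, plus a
carbonate band.

## XRD crystallite sizing

Patterns span 20–45° 2θ at the instrument's 0.0334° step (Cu Kα,
λ = 0.15406 nm).  A linear background through the window endpoints is
removed, a single Gaussian fitted (the profile shape is a modeling
choice; Gaussian keeps FWHM closed-form), and the Scherrer relation
`size = K·λ/(FWHM_rad·cos θ)` applied with K = 1 exactly as the source
equation is written (K = 0.9 available).  The 002 reflection near 26°
gives the crystallite length, the 310 reflection near 40° the width.  A
peak whose baseline-corrected amplitude is below 3× the local noise is
"not detected".  If the fitted FWHM exceeds half the fit window the fit
is repeated over 3× the FWHM, which keeps the sizing identity within 1%
down to ~4 nm; below that the two reflections overlap on this scan range
and single-peak sizing is ill-posed.

## fAGE assay

Fluorescence (360/460 nm) is normalized against serially diluted quinine
standards (10 μg/mL stock; the generator plates use ten two-fold steps
plus a blank so the standards bracket the diluted sample reads);
hydroxyproline from the chloramine-T absorbance assay (570 nm, 2 mg/mL
stock) gives collagen via the 14% hydroxyproline mass fraction.
Standard curves are ordinary least-squares lines *with* intercept (plate
readers carry background) and must reach R² ≥ 0.95.  Back-calculated
concentrations are scaled by the explicit dilution factor (10× for the
fluorescence read) and the hydrolysate volume (100 μL of 6 N HCl per mg
bone); negative concentrations clamp to zero with a flag, out-of-range
reads are flagged as extrapolated.  Result: ng quinine equivalents per
mg collagen.  Zero-noise plate sets round-trip exactly; with 0.5%
multiplicative read noise the unweighted calibration over a three-decade
standard range leaves ~5% per-sample error, which the cohort-level
tests account for by error propagation.

## Voxel morphometry

Tissue mineral density uses the exact two-point line through the 200 and
800 mg/cc hydroxyapatite phantom gray values, averaged over the bone
mask.

Cortical (cylindrical mid-diaphyseal ROI, slices along the axis):
Ct.Ar = foreground count × voxel area; J = Σ r²·dA about the slice
centroid; Ct.Th = 2 × mean Euclidean distance transform on the medial
skeleton, where the skeleton is taken as the EDT distance ridge (local
maxima) — a thinning skeleton's voxel jitter biases the estimate low by
~2–3% on annulus phantoms, the ridge by under 1%.  Empty slices are
skipped with a flag.

Trabecular (cubical ROI): BV/TV is the foreground fraction;
Tb.Th / Tb.Sp are mean local thickness of fore-/background by the
largest-inscribed-sphere (distance-ridge) definition, computed by
binning ridge radii in half-voxel steps and painting each bin's spheres
with one distance transform (one EDT per bin rather than one sphere per
ridge voxel); Tb.N = (BV/TV)/Tb.Th, the plate-model estimator (other
estimators exist; this one is documented and configurable in reporting).
Thickness carries an inherent ≈ half-voxel quantization; parallel-plate
phantoms with even voxel counts recover thickness and separation
exactly.

Generator volumes: cortical bone is a hollow cylinder parameterized by
Ct.Ar and Ct.Th (its analytic polar moment is the J truth — note a
circular annulus cannot independently realize an arbitrary J);
trabecular bone is either a parallel-plate stack (half-gap phase offset
so plates never touch the box boundary) or a thresholded smoothed
Gaussian random field whose threshold is the exact BV/TV quantile and
whose smoothing scale is self-calibrated (≤3 iterations) until the mean
local thickness is within 3% of target.

## Statistics

- **Outliers**: one pass per parameter; mean and sample SD computed once
  on the full input; points beyond 2 SD removed.  Not iterated (for
  determinism), not per-animal.  Groups below n = 3 skip the screen.
- **Test selection**: Lilliefors-style Kolmogorov–Smirnov (normal with
  sample mean/SD; the exact KS variant of the original toolchain is
  unknowable, so this choice is flagged in reports) per group and
  Levene's test across groups, both at α = 0.05.  Both groups normal and
  homoscedastic → Student t; normal but heteroscedastic → Welch t;
  otherwise exact Mann–Whitney U (verified against full enumeration for
  n₁+n₂ ≤ 10).  Below n = 4 normality is untestable and the
  distribution-free branch is used.
- **Percent differences** are control-referenced and signed:
  (control − T2D)/control × 100.
- **Pearson r** with two-sided p via the t transform; r² reported as
  variance explained.
- **Forward stepwise regression** (pure forward, no removal step): at
  each step the candidate with the smallest partial-F entry p-value
  below 0.05 joins; near-collinear candidates (condition number > 10⁸)
  are skipped with a warning.

## Synthetic cohort

Latent per-animal parameters are independent normals truncated at zero
(matching the mean ± SD summary form of the study conditions), with the
published group means and SDs for the metabolic covariates,
nanoindentation, crystallite sizes, fAGE and morphometry.  Bending, cRPI
and FTIR absolute levels are not published (shown only graphically), so
typical rat-femur values anchor the control group — F_max 130 N,
stiffness 320 N/mm, PYD 0.38 mm, F_yield = 0.85·F_max; ID-1st 70 μm,
IDI 15 μm, US-1st 0.55 N/μm, Avg-ED 30 μJ; mineral/matrix 3.5,
carbonate/phosphate 0.009, crystallinity 1.25, acid phosphate 0.72,
NE-xLR 1.5, maturity 3.0 — and the T2D means apply the published
percent differences exactly.  ID-1st and IDI are the primary cRPI
latents; TID is their sum, so its group difference follows from the
other two rather than being set independently (the three published
percentages are mutually over-determined).

Within the T2D group a single standard-normal "glycation severity"
factor per animal carries configurable loadings on NE-xLR (+0.835), PYD
(−0.835), fAGE (+0.913), crystallite width (+0.913), HbA1c (+0.80),
F_max (−0.885), BV/TV (−0.90) and Ct.Th (−0.85), reproducing the
published within-diabetic-group correlation structure (e.g.
r(NE-xLR, PYD) = −0.835² ≈ −0.697, so NE-xLR explains ≈ 48.6% of PYD
variance); control draws are independent, matching the absence of
significant control-group correlations.  This is a descriptive device,
not a mechanism.

Default noise amplitudes (relative): bending 0.002 of F_max, cRPI depth
0.001, nanoindentation 0 (instrument noise is negligible at this scale),
FTIR 5×10⁻⁴ absorbance, XRD Poisson-like with scale 0.5, plate reads
0.5%, volumes noise-free masks.  Everything is driven by one
`numpy.random.Generator`; identical (config, seed) runs are
byte-identical, including artifact files (paths are stored relative to
the output directory).

What the generator does **not** emulate: scanner physics (beam
hardening, partial volume, detector spectra), anatomical geometry
(cross-sections are circular annuli; trabecular architecture is a
stationary random field), viscoelasticity and creep in indentation,
non-Gaussian spectral line shapes, plate-edge effects, and any
biological remodeling.  Passing tests therefore demonstrate that the
analysis stages are correct inverses of well-defined instrument models
and that the statistical pipeline reproduces the published derived
quantities — not that the estimators are robust to every artifact of
real instruments.

## Problem sizes and runtime choices

The default study runs n = 10 per group with 6 cRPI sites and 8
nanoindents per animal.  Default voxel volumes are scaled to what the
morphometry estimators need rather than full scan fields of view:
trabecular 0.6 mm cube at 10 μm voxels, cortical 12 slices at 20 μm —
the estimators are resolution-convergent (tested), so larger volumes
change only runtime.  A full study completes in about half a minute on
one core.

## Known limitations

- The 0.2% offset's reference length (the span) is a convention; other
  labs use center-deflection-to-strain conversions.  It is configurable
  but changes PYD.
- Sub-band deconvolution inherits the usual identifiability caveats of
  overlapping-Gaussian fitting; results should be read together with the
  fit R² and the flagged zero-area bands.
- Scherrer sizing with K = 1 and no instrument-broadening correction
  reports apparent sizes; only differences between groups measured the
  same way are meaningful.
- Tb.Sp near the ROI boundary is biased by the open boundary (no
  boundary correction is applied, matching common practice).
- The exact Mann–Whitney p-value uses the permutation-exact method for
  tied data; SPSS's asymptotic-with-correction values can differ
  slightly in small samples.
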