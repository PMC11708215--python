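# Methods

## Scope

`ovotools` implements the quantitative analysis chain for in-vivo imaging of
Drosophila oogenesis: inferring a developmental timeline from fixed-sample
surveys, building and inverting exponential standard growth curves, 3D
nuclear segmentation, region-based normalized fluorescence quantification
(yolk uptake and histone redistribution during nurse-cell dumping), alignment
of live growth traces to the standard curve, and follicle-cell kinematics.
Because no raw microscopy is distributed, a first-class synthetic-data
module generates every input with known ground truth; all tests and the
reproduction script run on that synthetic data.

## Timeline inference

Under steady-state egg production, an ovariole of EO egg chambers emitting
EPR = E/O eggs per day (E eggs/female/day, O ovarioles/female) moves a
chamber from stage 2 to stage 14 in G = EO/EPR days (reported in hours).
The observed frequency f_s of stage s among fixed chambers estimates the
fraction of G spent in that stage, so Gs = f_s · G. Assumptions: production
is stationary over the sampling window and fixation samples chambers
uniformly in time.

**Rounding.** All intermediates are carried at full precision; display
rounding (EPR to 2 decimals, G to whole hours) happens only in
`format_report`. This matters: with E = 51.5, O = 35.63, EO = 5.2 the chain
gives EPR = 1.4454…, G = 86.34 h and Gs for stage 8 (f = 0.077) of
0.077 × 86.34 = 6.65 h; rounding G to 86 first would give 6.62 h.

## Growth curves

Chamber size is summarised by the midsection area A (µm², the widest
cross-section), growing as A(t) = A₀·e^{kt} with the standard constants
A₀ = 273 µm², k = 0.06 /h. The oocyte's share of the midsection follows its
own exponential, O(t′) = 0.318·e^{0.07t′}. Since O ≈ 0.30 marks stage-8
completion and the curve's amplitude is 0.318, the package fixes the
oocyte-percent time origin t′ = 0 at stage-9 onset; all oocyte-based ages
live on that axis. Fitting is ordinary least squares of ln(value) on age
(a multiplicative, lognormal error model), which is deterministic and
matches how area noise is generated. Fit points use each chamber's
stage-midpoint age — the unbiased within-stage placement given only a stage
call. Oocyte-percent fits use vitellogenic chambers (stages 8–11) and drop
near-saturated fractions (≥ 0.9), where the percent plateaus and leaves the
exponential regime. `predict` and `invert_time` are exact mutual inverses;
`invert_time` assigns the initial age t₀ of a live trace from its first
measured area (or oocyte percent, for chambers past the 30% boundary).

## Synthetic data

The generator's defaults are the study conditions: E = 51.5, O = 35.63,
EO = 5.2; per-female counts are Poisson around those means. Per-stage
frequencies for stages 2–14 are fixed once (sum 1, f₈ = 0.077, early stages
slightly more frequent than the brief dumping stages); only f₈ is an
observed constant, the rest are the package's choice of a plausible
distribution. Midsection areas are curve predictions at stage-midpoint ages
times lognormal noise with CV 0.1 by default (areas are positive and growth
multiplicative; no noise model is prescribed by the source data).

Chamber phantoms are prolate ellipsoids (AP axis along x, aspect 1.5,
optionally flattened in z to emulate compression) whose equatorial area
follows the standard curve at the phantom's age. Follicle nuclei sit in
per-slice rings just inside the surface; up to 15 nurse nuclei (a 16-cell
cyst minus the oocyte) are rejection-sampled without overlap in the anterior
interior; the oocyte is the posterior cap cut so that it occupies the
requested fraction of the midsection area (the cut can only move in
pixel-column steps, so the achieved fraction is exact to roughly one column).
Default voxel size is (z, y, x) = (3, 0.17, 0.17) µm, matching 3-µm z-steps
and 0.17-µm pixels; tests and the reproduction script use coarser voxels
(0.5–2 µm in-plane) to keep grids small, which is a resolution choice, not a
model change. Ground truth records every nucleus's centroid, radius,
voxelized volume (exactly voxel count × voxel volume) and noise-free
integrated intensity; doubling a channel gain doubles integrated intensities
exactly. Optics are idealised: no PSF, no depth attenuation, additive
Gaussian noise only.

Nurse-cell dumping is a linear four-compartment chain
nuclei → nurse cytoplasm → anterior oocyte → posterior oocyte with rate
constants k_nuc_out, k_ncc_ao, k_ao_po (defaults 1.5, 2.0, 1.2 /h over 4 h —
a dumping-scale timecourse in which each intermediate series rises and
falls within the window). The chain is integrated exactly by the matrix
exponential of the rate matrix (columns sum to zero, so total signal is
conserved to machine precision); forward Euler is retained only as a
cross-check, with an explicit rate·dt < 1 stability guard. Nuclear *volume*
decays independently at nuclear_shrink_rate (default 2.0 /h); because it
exceeds the intensity-loss rate, nuclear concentration rises transiently —
the hallmark the region quantifier must reproduce. A shrinking nucleus never
drops below one voxel, so series don't terminate by rendering artifact.
Frames paint each compartment at uniform concentration (total/voxel count),
making zero-noise frame sums match the ODE exactly. The anterior oocyte is
rendered as the anterior 40% of the oocyte's AP extent — far enough
posterior that the "within 17 µm of the posterior border" ROI never
straddles the split.

Rotation tracks place cells on a chamber rotating about the AP axis at ω
degrees/hour; a cell at phase φ projects to y = y_mid + r·sin φ. Initial
phases are symmetric about the midline so default-length tracks stay in the
small-angle regime where the arctan estimator is accurate.

## 3D segmentation

The macro sequence is reproduced literally: separable Gaussian blur with
sigma in (x_px, y_px, z_slices) order (default (5, 5, 1), i.e. pixel units);
a single global Otsu threshold from a 256-bin histogram (foreground strictly
above threshold; ties across empty-bin plateaus break toward the lower
threshold, with a 1e-12 relative tolerance absorbing round-off); then erode,
dilate, open, close, fill-holes in exactly that order with a radius-1 ball
(hole filling per z-slice first, then 3D); 26-connected labeling with a
27-voxel (3×3×3) size floor. Every measurement — volume, centroid, total and
mean intensity — is taken from the raw, unprocessed voxels; blur and
morphology shape the mask only, so any parameter change that leaves the
final label set unchanged leaves measurements bit-identical. Coordinates are
0-based (t, z, y, x); areas and volumes are always calibrated (µm², µm³).

The chamber midsection is automated as the per-slice filled convex hull of
follicle-nucleus centroids (or of a binary chamber mask), taking the slice
of maximal hull area. Chambers are near-convex through stage 10, so the hull
is a faithful stand-in for a hand-drawn outline; a ring of n in-slice
centroids underestimates the true ellipse by the inscribed-polygon factor
(≈ 2% at n = 20), and ring centers sit at 0.98 of the boundary, so the
recovered area runs ~4–6% low — inside the 10% envelope asserted on
phantoms. Frame registration is integer-pixel translation maximizing the
circular cross-correlation of mean-subtracted maximum-intensity projections.
A bicubic z-resampling (factor 3) exists for rendering only; measurements
never use the resampled grid.

Touching nuclei are not split (no seeded watershed); phantoms for counting
tests therefore use well-separated nurse nuclei, and densely packed follicle
rings are excluded from count assertions — a property of the phantom, not
the segmenter.

## Region quantification

All reported intensities are ratios against the follicle-cell signal of the
same frame: total follicle intensity for yolk totals, mean follicle-voxel
intensity for regional concentrations. Any global per-frame gain (exposure,
bleaching) cancels exactly. Yolk totals sum raw voxels over the oocyte mask
from the top surface through the midsection slice, since deeper slices of
vitellogenic chambers are not imageable.

Square ROIs (default 20×20 px) sample 3 z-slices stepping 3 µm, starting
9 µm below the follicle border. Each region's constraints follow its
definition: NCC inside nurse cytoplasm within 17 µm of the oocyte border;
AO inside the oocyte within 17 µm of the nurse–oocyte border; PO inside the
oocyte within 17 µm of the posterior border, taken per-slice (the 3D
posterior pole can lie below the sampled depth). Proximity is judged
in-plane on the middle sampled slice, as the definitions are drawn on a
slice. Boxes must be entirely nucleus-free across all sampled slices.
Placement is deterministic where the original workflow was manual: among
admissible positions, the one maximizing distance to the nearest nuclear
voxel wins, ties broken by smallest (y, x). Time series sample every fifth
frame by default. Nurse-nuclear signal is reported both as total intensity
and as concentration (total/volume); a vanished nucleus terminates the
concentration series with a flag.

The 20×20 px ROI's physical size always comes from stack metadata. The
source protocol quotes both "20 × 20 pixel (428.5 µm²)" (≈1.04 µm/px) and
"100 pixels (17 µm)" (0.17 µm/px); the package does not reconcile the two —
calibration is metadata-driven throughout, and 17 µm is kept as the distance
constraint.

## Growth-trace alignment

t₀ is defined by the first sample only, so alignment is translation-
equivariant and never re-fits per-trace growth rates. `by='auto'` aligns by
area until the first frame's oocyte fraction reaches 0.30 (stage-8
completion), then by oocyte percent — late growth is yolk-driven and the
oocyte percent is the more reliable clock there. `percent_of_expected` is
scale-free under joint rescaling of areas and curve amplitude; cohort means
interpolate per-trace fractions linearly in elapsed time and report how many
traces cover each time point. Compression of chambers in the mount (which
makes midsection area underestimate volume) is documented, not modeled.

## Kinematics

θ = arctan((y − y_mid)/r)·180/π is implemented exactly as stated; it is a
projection approximation, so samples with |y − y_mid| > 0.9 r trigger a
warning. (In the source the formula's units annotation reads "degree/hour",
which can only describe Δθ/Δt, not θ itself; θ is degrees here.) Angular
velocity is the arithmetic mean of per-interval Δθ/Δt; mean speed the mean
per-interval Euclidean step over Δt, in µm/min. On simulated uniform
rotation the estimator recovers ω to within a few percent in the small-angle
regime; the arctan compression makes it a slight underestimate, growing with
track angular span (≈3% at ±14°).

## Numerical choices and degenerate inputs

- Day→hour factor fixed at 24; stage domain fixed to 2–14 (germarium and
  stage 1 excluded).
- Zero/negative ovarioles, non-positive EPR, non-positive areas or values,
  degenerate fit ages, constant volumes under Otsu, empty masks, zero
  follicle references and sub-2-sample tracks all raise `ValueError` with a
  message naming the constraint; impossible nurse-nucleus packings raise
  `RuntimeError` after bounded retries.
- All generators are deterministic given their seed (NumPy `default_rng`).

## What passing tests do and do not show

The synthetic data reproduces the *statistical structure* the analysis
assumes: Poisson counts, lognormal area noise, exponential growth, uniform
rotation, first-order compartment flux, binary-intensity nuclei. Passing
tests show the estimators are correct under those assumptions and
numerically stable at realistic parameter values. They do not show
robustness to optical blur, depth-dependent attenuation, staging errors,
chamber deformation, or touching-nucleus merging — none of which the
phantoms contain. Cohort-level animal results (survival, fecundity,
degeneration rates, the 95%/72% growth fractions) depend on the animals and
are out of reach of synthetic reproduction; the corresponding code paths are
exercised at property level instead.

## Problem sizes used in tests and the reproduction script

Surveys: 32 females (~500 chambers) for area-curve recovery; 200 females for
the oocyte-percent curve (its fit sees only three distinct stage ages, so
timeline-estimation noise dominates at small n); 10⁴ females only for
law-of-large-numbers checks. Phantoms: single chambers of a few hundred
thousand voxels at 0.5–2 µm in-plane resolution. Dumping: 21 frames at
0.2 h steps, quantified at stride 2. Rotation: 5 cells, 1 h at 10-min
intervals.
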