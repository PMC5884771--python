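# Methods

## Radial profiling

An `AFImage` is an 8-bit grayscale array with landmarks in pixel
coordinates (x right, y down, origin at the top-left pixel center):
fovea, optic-disc center, disc radius, laterality, modality (SW or
NIR) and a degrees-per-pixel scale (default 30°/768 px ≈ 0.0390625,
the 30° confocal SLO field; overridable per image).

For every integer radius r = 1..R the mean intensity along each
hemicircle is computed by bilinear interpolation at angular steps of
arc length ≤ 1 pixel. Sample points exactly on the vertical meridian
through the fovea are excluded from both hemifields (half-open angular
bins; a measure-zero tie set). The left semicircle is sampled as the
exact mirror of the right, so flipping an image left–right swaps the
nasal/temporal profiles to machine precision — a tested invariant.
Interpolated circle sampling agrees with an exhaustive per-pixel
radius-binning oracle within 0.5 gray level on smooth images.

**Radius limit.** R is the smaller of the fovea-to-disc-center
distance and the largest radius whose full circle fits in the image.
This guarantees every sample stays inside the picture and no circle
passes the disc center; with typical landmark geometry it lands in the
160–200 px range.

**Normalization.** `AF(r) = (AF_measured(r) − AF_ref)/(AF_mean −
AF_ref)`, where `AF_ref` is the mean over a circular optic-nerve-head
ROI (radius 15 px by default; the nerve head is where AF is
physiologically minimal) and `AF_mean` is the full-image mean. Disc
pixels are *not* masked from `AF_mean` (no masking rule is standard; a
config flag could add one, and the normalization is insensitive to it
at the percent level). Any gray-level gain/offset applied to all
pixels cancels algebraically — normalized profiles are invariant to
machine precision provided no 8-bit clipping occurs (tested). A
constant image has `AF_mean = AF_ref` and raises a degenerate-
normalization error.

Profiles are resampled by linear interpolation onto a fixed 0.05° grid
spanning (0, R·scale]; below the innermost native sample (1 px) the
value is held constant.

**Control band.** The normative envelope is the pointwise mean and
sample SD (n−1) over ≥ 2 control eyes, each eye contributing the
average of its two hemifields, on the profiles' common grid. The study
design uses eight age-matched healthy right eyes.

## Lesion metrics

Profiles are smoothed with a 0.25° moving average before detection
(plots of this kind are visibly smoothed; the window is a parameter).
Detection thresholds use the control envelope at ± 1 SD (multiplier
configurable).

*SW-AF perifoveal ring*: present iff each hemifield has a contiguous
span ≥ 0.25° within 0.3–8° eccentricity where the smoothed profile
exceeds mean + SD. Diameter = nasal peak-excess eccentricity +
temporal peak-excess eccentricity (peak-to-peak; whether human graders
measured edge-to-edge or peak-to-peak is not recorded, so this is this
package's definition, chosen because the phantom truth is recovered
exactly for symmetric ring profiles).

*NIR-AF central hypoautofluorescence*: per hemifield, the smoothed
minimum over 0–3° is classified: below mean − SD → definite; at or
below mean − 0.5·SD → ill-defined; else none. Overall status is
`present` (both definite), `absent` (either hemifield shows no dip),
otherwise `borderline`. The 0.5 fraction exists so that a healthy
profile grazing the band mean is not called borderline; it is a
parameter. Diameter (present only) = sum of the per-hemifield
eccentricities where the smoothed profile re-crosses the lower
envelope from below, scanning outward from the minimum, with sub-grid
linear interpolation of the crossing.

Two-observer workflows average diameters arithmetically only when
statuses agree; conflicting statuses raise an error rather than being
silently resolved.

## Phantoms and ground truth

The image model is radially symmetric about the fovea:
`I = clip(vignette · [baseline + foveal term + ring bump − core dip],
0, 255)` with the disc rendered as a near-zero filled circle (soft
~1 px edge to avoid aliasing), then optional horizontal box blur
(nystagmus produces predominantly horizontal fixation artifacts; no
quantitative model is attempted), then additive Gaussian noise and
8-bit quantization. The foveal term is a Gaussian depression (SW,
depth 70, σ 0.8°) or peak (NIR, amplitude 60, σ 1.2°); the ring is a
Gaussian bump in eccentricity (σ 0.3°); the core is a logistic-edged
plateau (edge 0.08°). Smooth cross-sections make crossing-based
diameters well defined. The vignette is fovea-centered and quadratic
(strength 0.25), preserving the radial symmetry that makes analytic
azimuthal means exact.

Truth: the ring diameter is 2·ring_ecc exactly (symmetric smoothing
preserves peak position). The hypoautofluorescence diameter is defined
*operationally*: the package's own crossing rule applied to the
noiseless analytic profile against an ideal band (the lesion-free
analytic profile as mean, constant SD = `truth_band_sd`, default 0.03
in normalized units, matching the spread the control perturbations
produce). This makes truth and measurement share smoothing and
threshold conventions, so recovery error isolates noise and sampling;
the tested budget is ± 0.2° at noise σ = 2 gray levels over 20 seeds.

Controls perturb baseline (± 5%), dip/peak amplitude and width and the
vignette strength across eyes — pure gain/offset perturbations would
cancel under normalization and give a zero-width band.

**Cohort simulator.** Ages uniform on 8–45 years. A central NIR
hypoautofluorescent area is present with probability
`expit(0.18·(age − 23))` (chosen to give affected/unaffected mean ages
near 31 and 16 years at realistic prevalence); when present, the core
half-width is `softplus(−0.8 + 0.05·age)` degrees plus N(0, 0.1°)
noise — softplus keeps sizes positive and strictly increasing in age,
so the noise-free truth table has Spearman(age, diameter) = 1 among
affected records. The ISe defect width is `1.0 × diameter +
N(0, 0.15°)` floored at 0, and the four-level OCT stage is graded from
it (0 → stage 1; < 0.8° → 2; < 1.6° → 3; else 4). A perifoveal SW ring
occurs with probability 0.75 at eccentricity N(0.75°, 0.15°). With
`render=True` the SW/NIR image pair of each case is synthesized; with
`render=False` only the truth table is produced (identical record
stream), which is what the 200-seed null-calibration simulations use.

What the phantoms do *not* emulate: optics/PSF realism, fluorophore
physiology, inter-eye asymmetry, fixation-dependent landmark error,
and OCT B-scans (the ISe width is generated directly as a number).
Passing recovery tests therefore demonstrate correctness of the
measurement chain under the stated image model, not clinical accuracy
on device data.

## Statistics

All tests report raw p-values; no multiple-testing correction is
applied anywhere (results are interpreted against α = 0.05, matching
the reporting convention of the underlying study design).

* **Spearman**: Pearson correlation of midranks; two-sided p from the
  t-approximation with n − 2 df (exact permutation with ties is
  impractical at n = 16; the approximation is documented and the rank
  computation is oracle-tested against an independent implementation).
* **Mann–Whitney (exact)**: U from midranks; p by complete enumeration
  of all C(n1+n2, n1) group assignments of the observed pooled values,
  so ties are handled by permutation rather than an asymptotic
  correction; two-sided p = 2·min(tails), capped at 1. Enumeration is
  refused above n1+n2 = 20 — no silent approximation.
* **Fisher's exact**: one-sided = hypergeometric tail in the observed
  direction of association; two-sided = sum of table probabilities no
  larger than the observed one. In the NIR-group analysis the Fisher
  test defaults to one-sided (direction: more advanced OCT stages in
  the hypoautofluorescent group); both sidedness options are exposed.
* **Wilcoxon signed-rank (paired)**: zeros dropped; exact enumeration
  of all 2^n sign assignments for n ≤ 15, else normal approximation
  with tie correction.
* **ICC**: two-way random-effects, absolute-agreement, single measures
  (ICC(A,1)) from ANOVA mean squares, with the standard F-based 95% CI
  (Satterthwaite df). The agreement band is read off the *lower* CI
  bound: poor < 0.50 ≤ moderate < 0.75 ≤ good ≤ 0.90 < excellent
  ("substantial" is accepted as a synonym for good). Intra- and
  inter-observer designs use the same computation (columns are repeats
  or raters respectively).
* **Correlation matrix**: pairwise-deleted Spearman over age, LogMAR
  acuity (study eye), OCT stage, ISe width, ring diameter and
  hypoautofluorescence diameter; all-missing or constant columns are
  skipped with a warning; cells need ≥ 4 complete pairs.

## Numerical choices and degenerate inputs

Eccentricity grid step 0.05°; smoothing window 0.25° (5 grid points);
floating-point tie tolerance 1e−9 in enumeration tails; Spearman rho
snapped to ± 1 when within 1e−12 (rank arithmetic is rational).
Degenerate cases raise typed errors rather than returning NaN:
constant correlation input, empty Fisher margins, all-zero paired
differences, zero between-subject ICC variance, constant images under
normalization, fovea-on-border geometry, and observer status
disagreement.

## Problem sizes

Validation runs use 384×384 phantoms (the geometry of interest — the
central 6° — is unaffected by the crop), 8-control bands, 20-seed
recovery loops, a 60-case rendered cohort for pipeline-level
correlation recovery, and 200 truth-level replicates for null
calibration; the whole suite completes in well under a minute on one
CPU.

## Known limitations

The per-case study eye of the reference table is not identified
(10 right/6 left in aggregate); the fixture uses the right eye
throughout, which reproduces all published aggregate statistics.
Published inter-observer ICC values cannot be recomputed because the
raw two-observer measurements were never released; the ICC machinery
is validated by construction (oracle equality, perfect-agreement and
noise-degradation properties) instead. Whether the original plots
sampled true semicircles or split full circles post hoc is unknown;
semicircle sampling is used, a possible minor numerical difference.
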