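# semiqaf

Semiquantitative fundus-autofluorescence (AF) profiling for congenital
achromatopsia (ACHM), with the small-cohort statistics that go with it.

ACHM is a cone dysfunction syndrome (biallelic *CNGA3*, *CNGB3* or
*PDE6C* mutations in most cases) long regarded as stationary, but with
growing evidence of structural foveal progression — which matters now
that gene-replacement trials need imaging biomarkers. Short-wavelength
AF (SW-AF, lipofuscin-dominated) typically shows a perifoveal
hyperautofluorescent ring; near-infrared AF (NIR-AF,
melanin-dominated) may develop a central hypoautofluorescent area whose
size tracks age and the width of the inner-segment-ellipsoid (ISe)
defect on OCT. Both lesions are hard to read directly on AF images from
photophobic, nystagmic eyes; they become unambiguous on *semiquantitative
radial plots*.

## Method

For an 8-bit AF image with a marked fovea and optic-disc center, the
mean gray level `AF_measured(r)` is extracted along nasal and temporal
semicircles of radius `r = 1..R` pixels centered on the fovea (the
vertical meridian through the fovea splits the hemifields; the disc
side is nasal). With `AF_ref` the mean intensity over an optic-nerve-head
ROI (where AF is physiologically minimal) and `AF_mean` the whole-image
mean, each profile is normalized as

```
AF(r) = (AF_measured(r) − AF_ref) / (AF_mean − AF_ref)
```

so the nerve head maps to 0, the image average to 1, and any gray-level
gain/offset cancels exactly. Eccentricity is converted to visual
degrees (default 30°/768 px) and profiles are compared with a
pointwise mean ± SD envelope from eight healthy control eyes. Lesions
are then measured in degrees on the plots: ring diameter as the sum of
the nasal and temporal eccentricities of maximal excess above the upper
envelope; central NIR-AF hypoautofluorescence diameter as the summed
eccentricities at which the profile re-crosses the lower envelope, with
an explicit *borderline* category for ill-defined central decreases.

Because the original acquisitions are not public, the package includes
a phantom generator (`semiqaf.phantoms`) producing SW/NIR image pairs
with known lesion geometry, vignetting, nystagmus-like blur and noise,
plus a cohort simulator with age-linked lesion structure — every
pipeline stage is validated by ground-truth recovery. The 16-patient
clinical reference table is packaged (`semiqaf.fixture_table2()`), and
the statistics layer provides tie-aware exact Mann–Whitney and Wilcoxon
tests (complete enumeration), Fisher's exact test, Spearman
correlations, and absolute-agreement ICC with CI-based agreement bands.

## Worked example

```python
import semiqaf as sq
from semiqaf.phantoms import PhantomSpec, gen_af_phantom, control_band

# synthesize a NIR-AF acquisition with a 0.8 deg-half-width central
# hypoautofluorescent core, and measure it back
spec = PhantomSpec(modality="NIR", hypo_core_ecc=0.8, noise_sigma=2.0, seed=5)
image, truth = gen_af_phantom(spec)
profile = sq.profile_image(image)
band = control_band(PhantomSpec(modality="NIR"), n=8, seed=43)
status, diameter = sq.detect_central_hypoaf(profile, band)
print(f"truth diameter : {truth.hypo_diameter_deg:.2f} deg ({truth.hypo_status})")
print(f"measured       : {diameter:.2f} deg ({status})")

# clinical reference cohort: NIR-AF group comparison
rep = sq.nir_group_analysis(sq.fixture_table2())
print(f"age  {rep.mean_age_present:.1f} +/- {rep.sd_age_present:.1f} vs "
      f"{rep.mean_age_absent:.1f} +/- {rep.sd_age_absent:.1f} yr, "
      f"exact MW p = {rep.mann_whitney.p_value:.3f}")
```

prints

```
truth diameter : 2.04 deg (present)
measured       : 1.96 deg (present)
age  31.4 +/- 9.3 vs 15.6 +/- 6.7 yr, exact MW p = 0.004
```

i.e. the pipeline recovers the phantom's ground-truth lesion diameter
within less than 0.1°, and patients with a central NIR-AF
hypoautofluorescent area are significantly older than those without.

A command-line interface mirrors the library:
`semiqaf profile|band|measure|simulate|cohort-stats|summary-report`
(see `semiqaf --help`).

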