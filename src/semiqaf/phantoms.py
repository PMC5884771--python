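"""Synthetic fundus-autofluorescence phantoms with ground truth.

Real acquisitions from the clinical cohort were never deposited, so the
package ships a generator that emulates their salient structure for
validation: a radially symmetric intensity model about the fovea with

* SW modality: a central Gaussian depression (foveal masking of the
  lipofuscin signal) and an optional perifoveal hyperautofluorescent
  ring (Gaussian bump in eccentricity);
* NIR modality: a central macular hyperautofluorescent peak (melanin)
  and an optional central hypoautofluorescent core — a logistic-edged
  plateau of half-width ``hypo_core_ecc``;

plus a dark optic disc (autofluorescence is physiologically minimal on
the nerve head, which is what makes it the normalization reference), a
fovea-centered quadratic vignette, optional horizontal box blur
emulating nystagmus-like fixation instability, and additive Gaussian
noise, quantized to 8 bits.

Ground truth: the ring diameter is ``2 * ring_ecc`` exactly; the
hypoautofluorescence diameter is defined operationally, by applying the
package's own crossing rule to the noiseless analytic profile against
an ideal control band (the lesion-free analytic profile with a constant
SD of ``truth_band_sd``), so that pipeline recovery error reflects
noise and sampling rather than model bias.

A cohort simulator (:func:`gen_cohort`) layers the statistical
structure the analysis assumes on top of the image model: the
probability of a central NIR hypoautofluorescent area rises with age
(logistic), its size grows with age, and the OCT
inner-segment-ellipsoid defect width tracks the hypoautofluorescence
diameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.special import expit

from .cohort import CohortTable, PatientRecord, Snellen
from .lesions import detect_central_hypoaf
from .profiles import (AFImage, ControlBand, RadialProfile,
                       DEFAULT_SCALE_DEG_PER_PX, GRID_STEP_DEG,
                       determine_radius_limit, profile_image)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "gen_af_phantom",
    "analytic_profile",
    "gen_control_phantoms",
    "control_band",
    "gen_cohort",
    "CohortSim",
    "SimulatedCase",
]

_DISC_LEVEL = 2.0  # gray level of the rendered optic disc interior


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic autofluorescence acquisition.

    Geometry defaults give a 384x384 crop at the 30-degree-field scale
    (0.0390625 deg/px) with the fovea 200 px temporal to the disc.
    Amplitudes are 8-bit gray levels; eccentricities, sigmas and widths
    are degrees.
    """

    width: int = 384
    height: int = 384
    scale: float = DEFAULT_SCALE_DEG_PER_PX
    fovea: tuple[float, float] = (140.0, 192.0)
    disc_center: tuple[float, float] = (340.0, 192.0)
    disc_radius: float = 28.0
    modality: str = "SW"
    laterality: str = "OD"
    baseline: float = 150.0
    fovea_dip_depth: float = 70.0    # SW central depression
    fovea_dip_sigma: float = 0.8
    peak_amp: float = 60.0           # NIR central macular peak
    peak_sigma: float = 1.2
    ring_ecc: float | None = None
    ring_width: float = 0.3          # Gaussian sigma of the ring bump
    ring_amp: float = 0.0
    hypo_core_ecc: float | None = None
    hypo_core_depth: float = 60.0
    hypo_core_edge: float = 0.08     # logistic edge softness (degrees)
    vignette_strength: float = 0.25  # 0..1, quadratic, fovea-centered
    noise_sigma: float = 2.0
    blur_len: int = 0                # horizontal box blur (pixels)
    truth_band_sd: float = 0.03      # ideal-band SD for the truth rule
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("SW", "NIR"):
            raise InvalidSpecError("modality must be SW or NIR")
        if not (0.0 <= self.vignette_strength <= 1.0):
            raise InvalidSpecError("vignette_strength must be in [0, 1]")
        if self.noise_sigma < 0 or self.blur_len < 0:
            raise InvalidSpecError("noise_sigma and blur_len must be >= 0")
        fx, fy = self.fovea
        border_deg = min(fx, fy, self.width - 1 - fx,
                         self.height - 1 - fy) * self.scale
        for name, ecc in (("ring_ecc", self.ring_ecc),
                          ("hypo_core_ecc", self.hypo_core_ecc)):
            if ecc is not None and not (0 < ecc < border_deg):
                raise InvalidSpecError(
                    f"{name} = {ecc} outside (0, {border_deg:.2f}) degrees")
        lo, hi = self._intensity_range()
        if lo < 0.0 or hi > 255.0:
            raise InvalidSpecError(
                f"noiseless intensities [{lo:.1f}, {hi:.1f}] leave [0, 255]")

    def _intensity_range(self) -> tuple[float, float]:
        ecc = np.linspace(0.0, max(self.width, self.height) * self.scale, 2048)
        f = self.radial_model(ecc)
        return float(f.min()), float(f.max())

    # -- analytic building blocks ------------------------------------

    def radial_model(self, ecc_deg) -> np.ndarray:
        """Noiseless retinal intensity at eccentricity ``ecc_deg``
        (before vignette, disc, blur, noise)."""
        e = np.asarray(ecc_deg, dtype=float)
        if self.modality == "SW":
            f = self.baseline - self.fovea_dip_depth * np.exp(
                -e ** 2 / (2 * self.fovea_dip_sigma ** 2))
        else:
            f = self.baseline + self.peak_amp * np.exp(
                -e ** 2 / (2 * self.peak_sigma ** 2))
        if self.ring_ecc is not None and self.ring_amp != 0:
            f = f + self.ring_amp * np.exp(
                -(e - self.ring_ecc) ** 2 / (2 * self.ring_width ** 2))
        if self.hypo_core_ecc is not None and self.hypo_core_depth != 0:
            f = f - self.hypo_core_depth * expit(
                (self.hypo_core_ecc - e) / self.hypo_core_edge)
        return f

    def vignette(self, dist_px) -> np.ndarray:
        """Fovea-centered quadratic vignette, 1 at the fovea."""
        fx, fy = self.fovea
        d_corner = max(math.hypot(fx - x, fy - y)
                       for x in (0, self.width - 1)
                       for y in (0, self.height - 1))
        d = np.asarray(dist_px, dtype=float)
        return 1.0 - self.vignette_strength * (d / d_corner) ** 2

    def lesion_free(self) -> "PhantomSpec":
        return replace(self, ring_ecc=None, ring_amp=0.0,
                       hypo_core_ecc=None)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    ring_diameter_deg: float
    hypo_diameter_deg: float
    hypo_status: str
    profile_noiseless: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _render_noiseless(spec: PhantomSpec) -> np.ndarray:
    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    fx, fy = spec.fovea
    d_px = np.hypot(xx - fx, yy - fy)
    img = spec.radial_model(d_px * spec.scale) * spec.vignette(d_px)
    # optic disc: near-zero filled circle with a ~1 px soft edge so the
    # rendered boundary is not aliased
    cx, cy = spec.disc_center
    d_disc = np.hypot(xx - cx, yy - cy)
    alpha = expit(spec.disc_radius - d_disc)
    return img * (1.0 - alpha) + _DISC_LEVEL * alpha


def _normalization_constants(spec: PhantomSpec, img: np.ndarray,
                             ref_radius_px: float = 15.0
                             ) -> tuple[float, float]:
    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    cx, cy = spec.disc_center
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= ref_radius_px ** 2
    return float(img[mask].mean()), float(img.mean())


def analytic_profile(spec: PhantomSpec, with_lesion: bool = True
                     ) -> RadialProfile:
    """Noiseless normalized radial profile implied by the spec.

    Normalization constants (AF_ref, AF_mean) are computed from the
    corresponding noiseless rendered image, mirroring the measurement
    pipeline.  Both hemifields are identical by construction.
    """
    s = spec if with_lesion else spec.lesion_free()
    img = _render_noiseless(s)
    af_ref, af_mean = _normalization_constants(s, img)
    geom = AFImage(np.zeros((s.height, s.width), np.uint8), s.modality,
                   s.laterality, s.scale, s.fovea, s.disc_center,
                   s.disc_radius)
    R = determine_radius_limit(geom)
    n_steps = int(math.floor(R * s.scale / GRID_STEP_DEG + 1e-9))
    grid = np.arange(1, n_steps + 1) * GRID_STEP_DEG
    f = s.radial_model(grid) * s.vignette(grid / s.scale)
    af = (f - af_ref) / (af_mean - af_ref)
    return RadialProfile(grid, af.copy(), af.copy(),
                         source={"modality": s.modality, "analytic": True})


def _truth_for(spec: PhantomSpec) -> PhantomTruth:
    ring_d = 0.0
    if spec.ring_ecc is not None and spec.ring_amp > 0:
        ring_d = 2.0 * spec.ring_ecc
    hypo_status, hypo_d = "absent", 0.0
    if spec.hypo_core_ecc is not None and spec.hypo_core_depth > 0:
        lesion = analytic_profile(spec, with_lesion=True)
        free = analytic_profile(spec, with_lesion=False)
        band = ControlBand(free.ecc_deg, free.mean_hemifields,
                           np.full_like(free.ecc_deg, spec.truth_band_sd),
                           n_controls=2)
        hypo_status, d = detect_central_hypoaf(lesion, band)
        hypo_d = d if d is not None else 0.0
    params = {k: v for k, v in asdict(spec).items()
              if k not in ("width", "height", "seed")}
    return PhantomTruth(ring_d, hypo_d, hypo_status, params)


def gen_af_phantom(spec: PhantomSpec) -> tuple[AFImage, PhantomTruth]:
    """Render one phantom acquisition and its ground truth.

    Deterministic for a fixed spec (the seed drives the noise).
    """
    img = _render_noiseless(spec)
    if spec.blur_len > 1:
        img = uniform_filter1d(img, size=int(spec.blur_len), axis=1,
                               mode="nearest")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = AFImage(pixels, spec.modality, spec.laterality, spec.scale,
                    spec.fovea, spec.disc_center, spec.disc_radius,
                    image_id=f"phantom-{spec.modality}-{spec.seed}")
    return image, _truth_for(spec)


def gen_control_phantoms(n: int, base_spec: PhantomSpec | None = None,
                         seed: int = 0, perturb: float = 0.05
                         ) -> list[AFImage]:
    """Lesion-free control phantoms with perturbed shape parameters.

    Each control multiplies the baseline, the central dip/peak amplitude
    and sigma by independent factors 1 + perturb*N(0,1) (amplitudes use
    twice the relative spread of the baseline) and jitters the vignette
    strength, giving the control band a realistic nonzero spread.
    """
    if n < 2:
        raise ValueError("need n >= 2 controls (SD undefined otherwise)")
    base = (base_spec or PhantomSpec()).lesion_free()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        g = 1.0 + perturb * rng.normal(size=5)
        spec = replace(
            base,
            baseline=base.baseline * g[0],
            fovea_dip_depth=base.fovea_dip_depth * (1 + 2 * (g[1] - 1)),
            fovea_dip_sigma=base.fovea_dip_sigma * g[2],
            peak_amp=base.peak_amp * (1 + 2 * (g[1] - 1)),
            peak_sigma=base.peak_sigma * g[2],
            vignette_strength=float(np.clip(
                base.vignette_strength + 0.6 * perturb * rng.normal(),
                0.0, 1.0)),
            seed=int(rng.integers(2 ** 31)) if perturb > 0 else base.seed,
        )
        out.append(gen_af_phantom(spec)[0])
    return out


def control_band(base_spec: PhantomSpec | None = None, n: int = 8,
                 seed: int = 0, perturb: float = 0.05) -> ControlBand:
    """Control envelope from ``n`` simulated healthy eyes (default 8)."""
    images = gen_control_phantoms(n, base_spec, seed=seed, perturb=perturb)
    return _band_from_images(images)


def _band_from_images(images: Sequence[AFImage]) -> ControlBand:
    from .profiles import build_control_band
    return build_control_band([profile_image(im) for im in images])


# ---------------------------------------------------------------------------
# Cohort simulation


def _softplus(z: float, s: float = 0.1) -> float:
    return s * math.log1p(math.exp(z / s))


@dataclass(frozen=True)
class SimulatedCase:
    record_id: str
    sw: AFImage | None
    nir: AFImage | None
    truth: PhantomTruth | None


@dataclass(frozen=True)
class CohortSim:
    cohort: CohortTable
    cases: tuple[SimulatedCase, ...]


_BCVA_DENOMS = (80, 100, 125, 160, 200, 250, 400, 500)


def _stage_from_ise(ise: float) -> int:
    if ise < 0.05:
        return 1
    if ise < 0.8:
        return 2
    if ise < 1.6:
        return 3
    return 4


def gen_cohort(n: int, *, a: float = -0.8, b: float = 0.05, c: float = 1.0,
               eps: float = 0.1, delta: float = 0.15,
               hypo_age0: float = 23.0, hypo_slope: float = 0.18,
               ring_prob: float = 0.75, noise_sigma: float = 2.0,
               render: bool = True, seed: int = 0) -> CohortSim:
    """Simulate a cohort with the statistical structure under study.

    Age is uniform on 8..45 years.  A central NIR hypoautofluorescent
    area is present with probability ``expit(hypo_slope*(age - age0))``;
    when present its core half-width is ``softplus(a + b*age) +
    eps*N(0,1)`` degrees (softplus keeps it positive and strictly
    increasing in age, so with eps = delta = 0 and b > 0 the truth table
    has Spearman(age, diameter) = 1 among affected records).  The ISe
    defect width is ``c * hypo_diameter + delta*N(0,1)``, floored at 0,
    and the OCT stage is graded from it.  With ``render`` the SW/NIR
    image pair of every case is synthesized at ``noise_sigma``.
    """
    if n < 4:
        raise ValueError("need n >= 4 (correlations degenerate below)")
    if c <= 0 or b < 0 or eps < 0 or delta < 0:
        raise ValueError("require c > 0, b >= 0 and non-negative noise")
    rng = np.random.default_rng(seed)
    records = []
    cases = []
    for i in range(n):
        age = int(rng.integers(8, 46))
        present = bool(rng.random() < expit(hypo_slope * (age - hypo_age0)))
        core_ecc = None
        hypo_d = None
        if present:
            core_ecc = _softplus(a + b * age) + eps * float(rng.normal())
            if eps > 0:  # floor only guards against negative noisy draws
                core_ecc = max(core_ecc, 0.08)
            hypo_d = 2.0 * core_ecc
            ise = max(0.0, c * hypo_d + delta * float(rng.normal()))
        else:
            ise = max(0.0, 0.3 * float(rng.normal()))
        stage = _stage_from_ise(ise)
        if stage == 1:
            ise = 0.0
        ring = bool(rng.random() < ring_prob)
        ring_ecc = float(np.clip(rng.normal(0.75, 0.15), 0.35, 1.5)) \
            if ring else None
        denom_od = int(rng.choice(_BCVA_DENOMS))
        denom_os = int(rng.choice(_BCVA_DENOMS))
        rec = PatientRecord(
            id=f"S{i + 1:03d}",
            age=age,
            sex=str(rng.choice(["M", "F"])),
            gene=str(rng.choice(["CNGA3", "CNGB3"])),
            mutations=("simulated", "simulated"),
            photophobia=bool(rng.random() < 0.75),
            nystagmus=bool(rng.random() < 0.63),
            color_vision=str(rng.choice(["partial", "severe"])),
            bcva_od=Snellen(20, denom_od),
            bcva_os=Snellen(20, denom_os),
            se_od=round(float(rng.uniform(-7.0, 5.5)) * 4) / 4,
            se_os=round(float(rng.uniform(-7.0, 5.5)) * 4) / 4,
            oct_stage=stage,
            foveal_hypoplasia=bool(rng.random() < 0.5),
            swaf_ring=ring,
            niraf_hypo="present" if present else "absent",
            ise_width_deg=ise,
            ring_diameter_deg=2.0 * ring_ecc if ring_ecc else None,
            hypo_diameter_deg=hypo_d,
        )
        records.append(rec)
        # Seeds are drawn unconditionally so the record stream is
        # identical with and without rendering.
        sw_seed = int(rng.integers(2 ** 31))
        nir_seed = int(rng.integers(2 ** 31))
        if render:
            sw_spec = PhantomSpec(
                modality="SW",
                ring_ecc=ring_ecc,
                ring_amp=30.0 if ring else 0.0,
                noise_sigma=noise_sigma,
                seed=sw_seed,
            )
            nir_spec = PhantomSpec(
                modality="NIR",
                hypo_core_ecc=core_ecc,
                hypo_core_depth=60.0 if present else 0.0,
                noise_sigma=noise_sigma,
                seed=nir_seed,
            )
            sw_img, sw_truth = gen_af_phantom(sw_spec)
            nir_img, nir_truth = gen_af_phantom(nir_spec)
            truth = PhantomTruth(
                ring_diameter_deg=sw_truth.ring_diameter_deg,
                hypo_diameter_deg=nir_truth.hypo_diameter_deg,
                hypo_status=nir_truth.hypo_status,
                profile_noiseless={"sw": sw_truth.profile_noiseless,
                                   "nir": nir_truth.profile_noiseless},
            )
            cases.append(SimulatedCase(rec.id, sw_img, nir_img, truth))
        else:
            cases.append(SimulatedCase(rec.id, None, None, None))
    cohort = CohortTable(tuple(records), source=f"simulated(seed={seed})")
    return CohortSim(cohort, tuple(cases))
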