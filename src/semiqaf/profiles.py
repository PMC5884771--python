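"""Hemicircular radial intensity profiling of fundus autofluorescence.

The semiquantitative representation averages the 8-bit gray level of an
autofluorescence image along nasal and temporal semicircles centered on
the fovea, for every integer radius r = 1..R pixels.  Each per-radius
mean ``AF_measured(r)`` is normalized against the optic-nerve-head
reference ``AF_ref`` (where autofluorescence is physiologically minimal)
and the whole-image mean ``AF_mean``::

    AF(r) = (AF_measured(r) - AF_ref) / (AF_mean - AF_ref)

so that profiles from different acquisitions, gains and exposures are
comparable: the optic nerve head maps to 0 and the image average to 1.
Eccentricity is expressed in visual degrees via the device scale
(default 30 degrees over 768 pixels for a 30-degree confocal scanning
laser ophthalmoscope field).

A pointwise mean +/- SD envelope over healthy control eyes
(:class:`ControlBand`) provides the normative corridor that the lesion
detectors compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DEFAULT_SCALE_DEG_PER_PX",
    "GRID_STEP_DEG",
    "AFImage",
    "RawProfile",
    "RadialProfile",
    "ControlBand",
    "determine_radius_limit",
    "compute_raw_profile",
    "normalize_profile",
    "profile_image",
    "build_control_band",
    "write_profile_csv",
    "read_profile_csv",
    "write_band_csv",
]

#: 30-degree field imaged over 768 pixels (confocal SLO default).
DEFAULT_SCALE_DEG_PER_PX = 30.0 / 768.0

#: Fixed resampling step of normalized profiles, in degrees.
GRID_STEP_DEG = 0.05

#: Default radius (pixels) of the circular reference ROI on the optic
#: nerve head over which AF_ref is averaged.
DEFAULT_REF_RADIUS_PX = 15.0


class GeometryError(ValueError):
    """Landmark/ROI geometry incompatible with the image."""


class DegenerateNormalizationError(ValueError):
    """AF_mean equals AF_ref (constant image); normalization undefined."""


@dataclass(frozen=True)
class AFImage:
    """One grayscale autofluorescence acquisition with its landmarks.

    Coordinates are (x, y) with x to the right, y down, origin at the
    center of the top-left pixel (0-based).
    """

    pixels: np.ndarray
    modality: str            # "SW" or "NIR"
    laterality: str          # "OD" or "OS"
    scale: float             # degrees per pixel
    fovea: tuple[float, float]
    disc_center: tuple[float, float]
    disc_radius_px: float
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if self.modality not in ("SW", "NIR"):
            raise ValueError(f"modality must be SW or NIR, got {self.modality!r}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        h, w = px.shape
        for name, (x, y) in (("fovea", self.fovea),
                             ("disc_center", self.disc_center)):
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise GeometryError(f"{name} {x, y} outside the image")
        if tuple(self.fovea) == tuple(self.disc_center):
            raise GeometryError("fovea and disc center coincide")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RawProfile:
    """Per-radius hemicircular means plus the normalization references."""

    radii_px: np.ndarray
    mean_nasal: np.ndarray
    mean_temporal: np.ndarray
    af_ref: float
    af_mean: float
    R: int

    def __post_init__(self) -> None:
        if self.R < 1 or len(self.radii_px) != self.R:
            raise ValueError("R must be >= 1 and match radii_px")


@dataclass(frozen=True)
class RadialProfile:
    """Normalized AF(r) per hemifield on a fixed eccentricity grid."""

    ecc_deg: np.ndarray
    af_nasal: np.ndarray
    af_temporal: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.ecc_deg, dtype=float)
        if e.ndim != 1 or len(e) == 0 or e[0] <= 0 or np.any(np.diff(e) <= 0):
            raise ValueError("eccentricity grid must be strictly increasing "
                             "and start above 0")
        for v in (self.af_nasal, self.af_temporal):
            if np.asarray(v).shape != e.shape:
                raise ValueError("profile arrays must match the grid")
            if not np.isfinite(v).all():
                raise ValueError("profile values must be finite")

    @property
    def mean_hemifields(self) -> np.ndarray:
        return (np.asarray(self.af_nasal) + np.asarray(self.af_temporal)) / 2.0


@dataclass(frozen=True)
class ControlBand:
    """Pointwise mean +/- SD envelope of control-eye profiles."""

    ecc_deg: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be non-negative")
        if self.n_controls < 2:
            raise ValueError("a control band needs >= 2 controls")


def determine_radius_limit(image: AFImage) -> int:
    """Maximal profiling radius R in pixels.

    R is the smaller of (a) the fovea-to-disc-center distance and (b)
    the largest radius whose full circle stays inside the image, so no
    sample leaves the picture and no circle crosses the disc center.
    """
    h, w = image.shape
    fx, fy = image.fovea
    disc_dist = math.hypot(image.disc_center[0] - fx,
                           image.disc_center[1] - fy)
    fit = min(fx, fy, (w - 1) - fx, (h - 1) - fy)
    R = int(min(math.floor(disc_dist), math.floor(fit)))
    if R < 1:
        raise GeometryError("fovea too close to the image border (R < 1)")
    return R


def _semicircle_offsets(r: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit offsets (dx, dy) sampling the right semicircle of radius r
    at arc steps <= 1 pixel; the vertical meridian itself is excluded
    (half-open angular bins keep samples strictly off x = 0)."""
    n = max(4, int(math.ceil(math.pi * r)))
    theta = -math.pi / 2 + (np.arange(n) + 0.5) * (math.pi / n)
    return r * np.cos(theta), r * np.sin(theta)


def compute_raw_profile(image: AFImage, R: int | None = None,
                        ref_radius_px: float = DEFAULT_REF_RADIUS_PX,
                        ) -> RawProfile:
    """Hemicircular mean-intensity profile for radii 1..R.

    For each integer radius, intensity is sampled by bilinear
    interpolation along each semicircle at angular steps of arc length
    <= 1 pixel and averaged.  The vertical line through the fovea splits
    the hemifields: the half containing the disc center is nasal, the
    other temporal.  AF_ref is the mean gray level over a circular ROI
    of ``ref_radius_px`` centered on the disc; AF_mean is the mean of
    the full image.
    """
    if R is None:
        R = determine_radius_limit(image)
    if R < 1:
        raise ValueError("R must be >= 1")
    h, w = image.shape
    fx, fy = image.fovea
    dx_disc, dy_disc = image.disc_center[0] - fx, image.disc_center[1] - fy
    if dx_disc == 0:
        raise GeometryError("disc center lies on the vertical meridian; "
                            "hemifield assignment undefined")
    cx, cy = image.disc_center
    if (cx - ref_radius_px < 0 or cx + ref_radius_px > w - 1
            or cy - ref_radius_px < 0 or cy + ref_radius_px > h - 1):
        raise GeometryError("disc reference ROI clipped by the image border")
    if fx - R < 0 or fx + R > w - 1 or fy - R < 0 or fy + R > h - 1:
        raise GeometryError(f"circle of radius {R} leaves the image")

    img = image.pixels.astype(float)
    radii = np.arange(1, R + 1)
    mean_right = np.empty(R)
    mean_left = np.empty(R)
    for i, r in enumerate(radii):
        ox, oy = _semicircle_offsets(float(r))
        # Right half and its exact mirror on the left.
        vals_r = map_coordinates(img, [fy + oy, fx + ox], order=1)
        vals_l = map_coordinates(img, [fy + oy, fx - ox], order=1)
        mean_right[i] = vals_r.mean()
        mean_left[i] = vals_l.mean()

    nasal_is_right = dx_disc > 0
    mean_nasal = mean_right if nasal_is_right else mean_left
    mean_temporal = mean_left if nasal_is_right else mean_right

    yy, xx = np.mgrid[0:h, 0:w]
    disc_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= ref_radius_px ** 2
    af_ref = float(img[disc_mask].mean())
    af_mean = float(img.mean())
    return RawProfile(radii, mean_nasal, mean_temporal, af_ref, af_mean, int(R))


def normalize_profile(raw: RawProfile, scale: float,
                      source: dict | None = None) -> RadialProfile:
    """Normalize a raw profile and resample onto the fixed 0.05-degree grid.

    AF(r) = (AF_measured(r) - AF_ref) / (AF_mean - AF_ref), per
    hemifield; eccentricity is r * scale.  The output grid spans
    (0, R*scale] in steps of :data:`GRID_STEP_DEG` (linear
    interpolation; below the innermost sample the value is held).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    denom = raw.af_mean - raw.af_ref
    if abs(denom) < 1e-12:
        raise DegenerateNormalizationError(
            "AF_mean equals AF_ref; constant image cannot be normalized")
    ecc_native = raw.radii_px * scale
    n_steps = int(math.floor(ecc_native[-1] / GRID_STEP_DEG + 1e-9))
    if n_steps < 1:
        raise ValueError("profile extent smaller than one grid step")
    grid = np.arange(1, n_steps + 1) * GRID_STEP_DEG
    af_n = (raw.mean_nasal - raw.af_ref) / denom
    af_t = (raw.mean_temporal - raw.af_ref) / denom
    return RadialProfile(
        ecc_deg=grid,
        af_nasal=np.interp(grid, ecc_native, af_n),
        af_temporal=np.interp(grid, ecc_native, af_t),
        source=dict(source or {}),
    )


def profile_image(image: AFImage, R: int | None = None,
                  ref_radius_px: float = DEFAULT_REF_RADIUS_PX,
                  ) -> RadialProfile:
    """Convenience: raw hemicircular profile + normalization in one call."""
    raw = compute_raw_profile(image, R=R, ref_radius_px=ref_radius_px)
    return normalize_profile(
        raw, image.scale,
        source={"image_id": image.image_id, "modality": image.modality,
                "laterality": image.laterality},
    )


def build_control_band(profiles: Sequence[RadialProfile]) -> ControlBand:
    """Pointwise mean and sample SD over control profiles.

    The two hemifields of each control eye are averaged before pooling,
    so each eye contributes once per eccentricity.  Profiles are
    restricted to their common grid; disjoint grids are an error.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 control profiles (SD undefined)")
    lo = max(p.ecc_deg[0] for p in profiles)
    hi = min(p.ecc_deg[-1] for p in profiles)
    if hi < lo - 1e-9:
        raise ValueError("control profiles have disjoint eccentricity ranges")
    ref = profiles[0].ecc_deg
    grid = ref[(ref >= lo - 1e-9) & (ref <= hi + 1e-9)]
    stack = []
    for p in profiles:
        sel = np.isclose(p.ecc_deg[:, None], grid[None, :], atol=1e-9)
        idx = sel.argmax(axis=0)
        if not sel.any(axis=0).all():
            raise ValueError("control profiles are not on a common grid")
        stack.append(p.mean_hemifields[idx])
    arr = np.vstack(stack)
    return ControlBand(
        ecc_deg=grid,
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=1),
        n_controls=len(profiles),
    )


# ---------------------------------------------------------------------------
# CSV export


def write_profile_csv(profile: RadialProfile, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "ecc_deg": profile.ecc_deg,
        "af_nasal": profile.af_nasal,
        "af_temporal": profile.af_temporal,
        "modality": profile.source.get("modality", ""),
        "image_id": profile.source.get("image_id", ""),
    }).to_csv(path, index=False)


def read_profile_csv(path) -> RadialProfile:
    import pandas as pd

    df = pd.read_csv(path)
    src = {}
    if "modality" in df and len(df):
        src["modality"] = str(df["modality"].iloc[0])
    if "image_id" in df and len(df):
        src["image_id"] = str(df["image_id"].iloc[0])
    return RadialProfile(df["ecc_deg"].to_numpy(),
                         df["af_nasal"].to_numpy(),
                         df["af_temporal"].to_numpy(), source=src)


def write_band_csv(band: ControlBand, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "ecc_deg": band.ecc_deg, "mean": band.mean, "sd": band.sd,
        "n": band.n_controls,
    }).to_csv(path, index=False)
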