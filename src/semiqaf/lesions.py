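"""Detection and sizing of foveal autofluorescence lesions.

Two lesion types are measured on the normalized semiquantitative
profiles, each against the healthy-control envelope:

* the SW-AF perifoveal hyperautofluorescent ring — present when the
  smoothed profile exceeds ``mean + 1*SD`` of the control band over a
  contiguous perifoveal span in both hemifields; its diameter is the
  nasal peak eccentricity plus the temporal peak eccentricity
  (peak-to-peak);
* the NIR-AF central hypoautofluorescent area — present when the
  central minimum falls below ``mean - 1*SD`` in both hemifields; its
  diameter sums, per hemifield, the eccentricity at which the smoothed
  profile re-crosses the lower envelope from below.  A central dip that
  stays between the control mean and the lower envelope is *borderline*
  (an ill-defined central decrease).

Thresholds (band multiplier, smoothing window, search ranges) are
explicit parameters with the defaults used throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .profiles import ControlBand, RadialProfile, GRID_STEP_DEG

__all__ = [
    "LesionMeasure",
    "detect_ring",
    "detect_central_hypoaf",
    "average_observers",
    "measure_profiles",
    "SMOOTH_WINDOW_DEG",
    "RING_SEARCH_DEG",
    "HYPO_SEARCH_DEG",
]

#: Moving-average smoothing window applied to profiles before detection.
SMOOTH_WINDOW_DEG = 0.25

#: Eccentricity range searched for the perifoveal ring (degrees).
RING_SEARCH_DEG = (0.3, 8.0)

#: Eccentricity range searched for the central hypoautofluorescent
#: minimum (degrees).
HYPO_SEARCH_DEG = (0.0, 3.0)

#: Minimal contiguous supra-threshold span for a ring call (degrees).
RING_MIN_SPAN_DEG = 0.25


class ObserverDisagreementError(ValueError):
    """Two observers assigned conflicting lesion statuses."""


@dataclass(frozen=True)
class LesionMeasure:
    """Presence flags and diameters (degrees) for one eye's lesions."""

    ring_present: bool
    ring_diameter_deg: float | None
    hypo_status: str  # present / absent / borderline
    hypo_diameter_deg: float | None
    observer: str = ""

    def __post_init__(self) -> None:
        if self.hypo_status not in ("present", "absent", "borderline"):
            raise ValueError(f"bad hypo_status {self.hypo_status!r}")
        if self.ring_present != (self.ring_diameter_deg is not None):
            raise ValueError("ring diameter must be set iff ring present")
        if (self.hypo_status == "present") != (self.hypo_diameter_deg
                                               is not None):
            raise ValueError("hypo diameter must be set iff hypo present")
        for d in (self.ring_diameter_deg, self.hypo_diameter_deg):
            if d is not None and d < 0:
                raise ValueError("diameters must be >= 0")

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _smooth(values: np.ndarray, window_deg: float) -> np.ndarray:
    size = max(1, int(round(window_deg / GRID_STEP_DEG)))
    return uniform_filter1d(np.asarray(values, float), size=size,
                            mode="nearest")


def _band_on_grid(band: ControlBand, ecc: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    if ecc[0] < band.ecc_deg[0] - 1e-9 or ecc[-1] > band.ecc_deg[-1] + 1e-9:
        raise ValueError("control band does not cover the profile grid")
    return (np.interp(ecc, band.ecc_deg, band.mean),
            np.interp(ecc, band.ecc_deg, band.sd))


def detect_ring(profile: RadialProfile, band: ControlBand,
                sd_multiplier: float = 1.0,
                smooth_window_deg: float = SMOOTH_WINDOW_DEG,
                search_deg: tuple[float, float] = RING_SEARCH_DEG,
                min_span_deg: float = RING_MIN_SPAN_DEG,
                ) -> tuple[bool, float | None]:
    """Detect the SW-AF perifoveal hyperautofluorescent ring.

    Returns ``(present, diameter_deg)``; the diameter is the sum of the
    nasal and temporal eccentricities of maximal excess above the upper
    control envelope (peak-to-peak), or None when absent.
    """
    ecc = profile.ecc_deg
    mean, sd = _band_on_grid(band, ecc)
    upper = mean + sd_multiplier * sd
    window = (ecc >= search_deg[0]) & (ecc <= search_deg[1])
    if not window.any():
        return False, None
    min_run = max(1, int(round(min_span_deg / GRID_STEP_DEG)))
    peaks = []
    for values in (profile.af_nasal, profile.af_temporal):
        excess = _smooth(values, smooth_window_deg) - upper
        excess = np.where(window, excess, -np.inf)
        above = excess > 0
        # longest contiguous supra-threshold run
        run = best = 0
        for flag in above:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best < min_run:
            return False, None
        peaks.append(float(ecc[np.argmax(excess)]))
    return True, peaks[0] + peaks[1]


def _recrossing(ecc: np.ndarray, values: np.ndarray, threshold: np.ndarray,
                start_idx: int) -> float:
    """First eccentricity at/after ``start_idx`` where ``values`` rises
    through ``threshold`` from below (linear interpolation between grid
    points; falls back to the profile end if it never re-crosses)."""
    below = values - threshold
    for i in range(start_idx, len(ecc) - 1):
        if below[i] < 0 <= below[i + 1]:
            frac = -below[i] / (below[i + 1] - below[i])
            return float(ecc[i] + frac * (ecc[i + 1] - ecc[i]))
        if below[i] >= 0:
            return float(ecc[i])
    return float(ecc[-1])


def detect_central_hypoaf(profile: RadialProfile, band: ControlBand,
                          sd_multiplier: float = 1.0,
                          borderline_fraction: float = 0.5,
                          smooth_window_deg: float = SMOOTH_WINDOW_DEG,
                          search_deg: tuple[float, float] = HYPO_SEARCH_DEG,
                          ) -> tuple[str, float | None]:
    """Detect and size the NIR-AF central hypoautofluorescent area.

    Per hemifield the smoothed profile's minimum over the central search
    range is classified against the control band: below
    ``mean - sd_multiplier*SD`` is a definite depression; a dip reaching
    at least ``borderline_fraction`` of the way down to that envelope is
    an ill-defined one (the fraction guards against calling the
    measurement noise of a healthy profile borderline).  The overall
    status is ``present`` when both hemifields show a definite
    depression, ``absent`` when either hemifield shows no dip, and
    ``borderline`` otherwise.  The diameter (present only) sums the
    per-hemifield eccentricities at which the smoothed profile
    re-crosses the lower envelope from below, scanning outward from the
    minimum.
    """
    ecc = profile.ecc_deg
    mean, sd = _band_on_grid(band, ecc)
    lower = mean - sd_multiplier * sd
    window = (ecc >= search_deg[0]) & (ecc <= search_deg[1])
    if not window.any():
        raise ValueError("profile does not cover the central search range")
    statuses = []
    radii = []
    for values in (profile.af_nasal, profile.af_temporal):
        smoothed = _smooth(values, smooth_window_deg)
        masked = np.where(window, smoothed - lower, np.inf)
        i_min = int(np.argmin(masked))
        shallow = mean[i_min] - borderline_fraction * sd_multiplier * sd[i_min]
        if smoothed[i_min] < lower[i_min]:
            statuses.append("present")
            radii.append(_recrossing(ecc, smoothed, lower, i_min))
        elif smoothed[i_min] <= shallow:
            statuses.append("borderline")
        else:
            statuses.append("absent")
    if all(s == "present" for s in statuses):
        return "present", radii[0] + radii[1]
    if any(s == "absent" for s in statuses):
        return "absent", None
    return "borderline", None


def average_observers(m1: LesionMeasure, m2: LesionMeasure) -> LesionMeasure:
    """Average two observers' diameters; statuses must agree."""
    if m1.ring_present != m2.ring_present or m1.hypo_status != m2.hypo_status:
        raise ObserverDisagreementError(
            f"observers disagree: ring {m1.ring_present}/{m2.ring_present}, "
            f"hypoAF {m1.hypo_status}/{m2.hypo_status}")

    def avg(a, b):
        return None if a is None else (a + b) / 2.0

    return LesionMeasure(
        ring_present=m1.ring_present,
        ring_diameter_deg=avg(m1.ring_diameter_deg, m2.ring_diameter_deg),
        hypo_status=m1.hypo_status,
        hypo_diameter_deg=avg(m1.hypo_diameter_deg, m2.hypo_diameter_deg),
        observer=f"mean({m1.observer},{m2.observer})" if m1.observer
        or m2.observer else "",
    )


def measure_profiles(sw: RadialProfile | None, nir: RadialProfile | None,
                     band_sw: ControlBand | None,
                     band_nir: ControlBand | None,
                     observer: str = "auto",
                     **kwargs) -> LesionMeasure:
    """Run both detectors on one eye's SW/NIR profile pair."""
    ring_present, ring_d = (False, None)
    if sw is not None and band_sw is not None:
        ring_present, ring_d = detect_ring(sw, band_sw, **kwargs)
    hypo_status, hypo_d = ("absent", None)
    if nir is not None and band_nir is not None:
        hypo_status, hypo_d = detect_central_hypoaf(nir, band_nir, **kwargs)
    return LesionMeasure(ring_present, ring_d, hypo_status, hypo_d,
                         observer=observer)
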