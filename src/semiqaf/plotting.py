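"""Combined SW/NIR semiquantitative plot rendering.

One panel per modality: nasal and temporal normalized profiles mirrored
about 0 degrees (temporal plotted at negative eccentricity), the
control mean +/- SD envelope shaded, and the OCT inner-segment-ellipsoid
defect width drawn as a central striped region.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .profiles import ControlBand, RadialProfile

__all__ = ["render_combined_plot"]


def _panel(ax, profile: RadialProfile, band: ControlBand | None,
           ise_width_deg: float, title: str) -> None:
    ecc = np.asarray(profile.ecc_deg)
    if band is not None:
        be = np.asarray(band.ecc_deg)
        for sign in (1.0, -1.0):
            ax.fill_between(sign * be, band.mean - band.sd,
                            band.mean + band.sd, color="0.8",
                            label="control mean ± SD" if sign > 0 else None)
    # Mirrored representation: nasal on the positive axis.
    ax.plot(ecc, profile.af_nasal, color="C0", label="nasal")
    ax.plot(-ecc, profile.af_temporal, color="C1", label="temporal")
    if ise_width_deg > 0:
        half = ise_width_deg / 2.0
        ax.axvspan(-half, half, facecolor="none", edgecolor="0.3",
                   hatch="///", linewidth=0.5, label="ISe defect")
    ax.axhline(1.0, color="0.6", linewidth=0.5)
    ax.axhline(0.0, color="0.6", linewidth=0.5)
    ax.set_title(title)
    ax.set_xlabel("eccentricity (degrees)")
    ax.set_ylabel("normalized AF")
    ax.legend(fontsize="small", loc="lower right")


def render_combined_plot(sw: RadialProfile, nir: RadialProfile,
                         band_sw: ControlBand | None = None,
                         band_nir: ControlBand | None = None,
                         ise_width_deg: float = 0.0,
                         path=None):
    """Render the two-panel semiquantitative plot; returns the Figure.

    Profile values are plotted exactly as given (no resampling at
    render time).  When ``path`` is set the figure is also written
    (PNG/SVG by extension).
    """
    if ise_width_deg < 0:
        raise ValueError("ise_width_deg must be >= 0")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    _panel(axes[0], sw, band_sw, ise_width_deg, "SW-AF")
    _panel(axes[1], nir, band_nir, ise_width_deg, "NIR-AF")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
    return fig
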