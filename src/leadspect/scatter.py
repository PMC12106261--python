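"""Triple-energy-window (TEW) scatter correction.

The scatter (plus down-scatter/penetration) contribution under the photopeak
is estimated by trapezoidal interpolation between two narrow flanking
windows:

    S = (C_lower / w_lower + C_upper / w_upper) * w_peak / 2

and the corrected counts are ``max(C_peak - S, 0)``.  For the Pb-212
photopeak at 239 keV the upper window also captures the down-scatter tail of
the high-energy daughter emissions, which is precisely why TEW (rather than
a dual-window estimate) is used for this pair.

Correction can be applied per pixel/voxel (arrays) or to VOI totals
(scalars); the formula is linear in the counts before clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import EnergyWindowSet

__all__ = ["TewInput", "scatter_estimate", "tew_correct", "tew_correct_volumes"]


@dataclass(frozen=True)
class TewInput:
    """Counts in the three windows plus their widths in keV."""

    c_peak: float
    c_lower: float
    c_upper: float
    w_peak_kev: float
    w_lower_kev: float
    w_upper_kev: float

    def __post_init__(self) -> None:
        for w in (self.w_peak_kev, self.w_lower_kev, self.w_upper_kev):
            if not w > 0:
                raise ValueError("window widths must be positive")
        for c in (self.c_peak, self.c_lower, self.c_upper):
            if c < 0:
                raise ValueError("counts must be non-negative")


def scatter_estimate(
    c_lower, c_upper, w_peak_kev: float, w_lower_kev: float, w_upper_kev: float
):
    """Trapezoidal scatter estimate under the photopeak (counts)."""
    if not (w_peak_kev > 0 and w_lower_kev > 0 and w_upper_kev > 0):
        raise ValueError("window widths must be positive")
    c_lo = np.asarray(c_lower, dtype=float)
    c_up = np.asarray(c_upper, dtype=float)
    s = (c_lo / w_lower_kev + c_up / w_upper_kev) * (w_peak_kev / 2.0)
    return float(s) if s.ndim == 0 else s


def tew_correct(x: TewInput) -> float:
    """Scatter-corrected photopeak counts, clamped at zero."""
    s = scatter_estimate(x.c_lower, x.c_upper, x.w_peak_kev, x.w_lower_kev, x.w_upper_kev)
    return max(x.c_peak - s, 0.0)


def tew_correct_volumes(
    peak: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    windows: EnergyWindowSet,
) -> np.ndarray:
    """Per-voxel TEW correction of matched photopeak/scatter-window images.

    All three arrays must share one grid; negative corrected values are
    clamped to zero before any downstream statistics (counts are
    non-negative).
    """
    peak = np.asarray(peak, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not (peak.shape == lower.shape == upper.shape):
        raise ValueError(
            f"window image grids differ: {peak.shape}, {lower.shape}, {upper.shape}"
        )
    s = scatter_estimate(
        lower,
        upper,
        windows.photopeak.width_kev,
        windows.lower_scatter.width_kev,
        windows.upper_scatter.width_kev,
    )
    return np.maximum(peak - s, 0.0)
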