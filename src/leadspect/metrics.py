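"""NEMA-style image-quality and quantification metrics.

Given a reconstructed (or reconstructed-like) count volume, the VOI scheme
and the phantom truth, this module computes:

* CRC  — contrast recovery coefficient per hot sphere,
  ``100 * (Ns/Nbg - 1) / (R_true - 1)`` (hot-sphere NEMA form),
* CNR  — contrast-to-noise ratio ``(Ns - Nbg) / sigma_bg`` where
  ``sigma_bg`` is, by default, the standard deviation of the 12 matched
  background-VOI means (voxel-level alternative behind a flag),
* CV_BG — background coefficient of variation over all voxels of the three
  large background cylinders (percent),
* ΔN_Lung — mean lung-insert counts over mean large-background counts
  (percent); the residual-count surrogate for septal penetration and
  down-scatter,
* CF  — camera calibration factor ``N_VOI / (V_VOI * t * Ā)`` (cps/MBq),
* RC  — recovery coefficient, measured over true activity concentration,
* FWHM — spatial resolution from the spherically averaged radial profile of
  a homogeneously filled sphere, fit with the closed-form ball⊗Gaussian
  model.

Background-free fills have no defined contrast ratio: CRC and ΔN_Lung are
reported as missing for them, mirroring the blank table cells such setups
produce.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

from .phantoms import PhantomSpec, VOISet, VoxelGrid, voi_stats
from .scatter import tew_correct_volumes

__all__ = [
    "VOIStats",
    "CalibrationResult",
    "FwhmResult",
    "IQReport",
    "crc",
    "cnr",
    "cv_bg",
    "lung_error",
    "calibration_factor",
    "recovery_coefficient",
    "ball_gaussian_profile",
    "radial_profile",
    "fwhm_from_sphere",
    "compute_voi_stats",
    "calibrate_on_cylinder",
    "analyze_iq",
]


@dataclass(frozen=True)
class VOIStats:
    """Count statistics feeding the contrast/noise metrics for one sphere size."""

    mean_sphere: float
    mean_bg: float
    sd_bg: float
    mean_bg_large: float
    sd_bg_large: float
    mean_lung: float

    def __post_init__(self) -> None:
        if self.sd_bg < 0 or self.sd_bg_large < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    """Camera calibration: counts → activity concentration conversion."""

    cf_cps_per_mbq: float
    n_voi: float
    v_voi_ml: float
    acq_time_s: float
    conc_true_mbq_ml: float

    def __post_init__(self) -> None:
        if not self.cf_cps_per_mbq > 0:
            raise ValueError("calibration factor must be positive")


@dataclass(frozen=True)
class FwhmResult:
    fwhm_mm: float | None
    sigma_mm: float | None
    converged: bool
    amplitude: float | None = None
    baseline: float | None = None


def crc(stats: VOIStats, true_ratio: float) -> float:
    """Contrast recovery coefficient (%): 100*(Ns/Nbg - 1)/(R_true - 1)."""
    if not true_ratio > 1:
        raise ValueError("true sphere-to-background ratio must exceed 1")
    if not stats.mean_bg > 0:
        raise ValueError("background mean must be positive")
    return 100.0 * (stats.mean_sphere / stats.mean_bg - 1.0) / (true_ratio - 1.0)


def cnr(stats: VOIStats) -> float:
    """Contrast-to-noise ratio: (Ns - Nbg) / sigma_bg."""
    if not stats.sd_bg > 0:
        raise ValueError("background standard deviation must be positive")
    return (stats.mean_sphere - stats.mean_bg) / stats.sd_bg


def cv_bg(stats: VOIStats) -> float:
    """Background coefficient of variation (%) over the large-cylinder voxels."""
    if not stats.mean_bg_large > 0:
        raise ValueError("large-background mean must be positive")
    return 100.0 * stats.sd_bg_large / stats.mean_bg_large


def lung_error(stats: VOIStats) -> float:
    """Relative lung-insert count error (%): 100 * mean_lung / mean_bg_large."""
    if not stats.mean_bg_large > 0:
        raise ValueError("large-background mean must be positive")
    return 100.0 * stats.mean_lung / stats.mean_bg_large


def calibration_factor(
    n_voi: float, v_voi_ml: float, acq_time_s: float, conc_true_mbq_ml: float
) -> CalibrationResult:
    """CF = N_VOI / (V_VOI * t * Ā), in cps/MBq."""
    if not (v_voi_ml > 0 and acq_time_s > 0 and conc_true_mbq_ml > 0):
        raise ValueError("VOI volume, time and true concentration must be positive")
    cf = n_voi / (v_voi_ml * acq_time_s * conc_true_mbq_ml)
    return CalibrationResult(cf, n_voi, v_voi_ml, acq_time_s, conc_true_mbq_ml)


def recovery_coefficient(conc_measured_mbq_ml: float, conc_true_mbq_ml: float) -> float:
    """RC = measured / true activity concentration."""
    if not conc_true_mbq_ml > 0:
        raise ValueError("true concentration must be positive")
    return conc_measured_mbq_ml / conc_true_mbq_ml


def counts_to_concentration(
    mean_counts_per_voxel: float, cal: CalibrationResult, acq_time_s: float, voxel_volume_ml: float
) -> float:
    """Convert a mean VOI count per voxel to MBq/ml through the CF."""
    return mean_counts_per_voxel / (cal.cf_cps_per_mbq * acq_time_s * voxel_volume_ml)


# ---------------------------------------------------------------------------
# spatial resolution from sphere radial profiles


def ball_gaussian_profile(r, radius: float, sigma: float):
    """Radial profile of a unit ball of ``radius`` convolved with an isotropic
    Gaussian of width ``sigma`` (both mm).

    Closed form:

        f(r) = 1/2 [erf((R-r)/(σ√2)) + erf((R+r)/(σ√2))]
               - σ/(r√(2π)) [exp(-(r-R)²/2σ²) - exp(-(r+R)²/2σ²)]

    ``f(0) → erf(R/(σ√2)) - R√(2/π)/σ · exp(-R²/2σ²)`` in the limit; small
    radii are clipped to keep the quotient well-conditioned.
    """
    r = np.maximum(np.asarray(r, dtype=float), 1e-9)
    s2 = sigma * math.sqrt(2.0)
    term1 = 0.5 * (erf((radius - r) / s2) + erf((radius + r) / s2))
    term2 = (
        sigma
        / (r * math.sqrt(2.0 * math.pi))
        * (np.exp(-((r - radius) ** 2) / (2 * sigma**2)) - np.exp(-((r + radius) ** 2) / (2 * sigma**2)))
    )
    return term1 - term2


def radial_profile(
    volume: np.ndarray,
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    r_max_mm: float,
    bin_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spherically averaged radial profile about ``center``: (radii, means)."""
    if bin_mm is None:
        bin_mm = grid.voxel_size_mm / 2.0
    x, y, z = grid.coords()
    r = np.sqrt((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2)
    inside = r <= r_max_mm
    r_in = r[inside]
    v_in = np.asarray(volume)[inside]
    bins = np.arange(0.0, r_max_mm + bin_mm, bin_mm)
    idx = np.digitize(r_in, bins) - 1
    n_bins = len(bins) - 1
    sums = np.bincount(idx, weights=v_in, minlength=n_bins)[:n_bins]
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    valid = counts > 0
    centers = (bins[:-1] + bins[1:]) / 2.0
    return centers[valid], sums[valid] / counts[valid]


def fwhm_from_sphere(
    volume: np.ndarray,
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    *,
    profile_margin_mm: float = 25.0,
) -> FwhmResult:
    """Spatial resolution (FWHM, mm) from a homogeneously filled sphere.

    Fits amplitude · ball⊗Gaussian(R fixed) + baseline to the spherically
    averaged radial profile; FWHM = 2√(2 ln 2)·σ.  A failed fit is reported
    with ``converged=False`` and missing numbers, never a fabricated value.
    """
    radii, prof = radial_profile(volume, grid, center_mm, radius_mm + profile_margin_mm)
    if radii.size < 5:
        return FwhmResult(None, None, False)
    amp0 = float(prof.max() - prof.min())
    base0 = float(prof.min())
    sigma0 = 2.0 * grid.voxel_size_mm

    def model(r, amplitude, baseline, sigma):
        return amplitude * ball_gaussian_profile(r, radius_mm, sigma) + baseline

    try:
        popt, pcov = curve_fit(
            model,
            radii,
            prof,
            p0=(amp0 if amp0 > 0 else 1.0, base0, sigma0),
            bounds=([0.0, -np.inf, 1e-3], [np.inf, np.inf, 60.0]),
            maxfev=20000,
            xtol=1e-10,
            ftol=1e-10,
        )
    except (RuntimeError, ValueError):
        return FwhmResult(None, None, False)
    amplitude, baseline, sigma = (float(v) for v in popt)
    if not np.all(np.isfinite(pcov)) or amplitude <= 0 or sigma >= 59.0:
        return FwhmResult(None, None, False)
    fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma
    return FwhmResult(fwhm, sigma, True, amplitude=amplitude, baseline=baseline)


# ---------------------------------------------------------------------------
# orchestration


def compute_voi_stats(
    volume: np.ndarray, vois: VOISet, diameter: float, *, voxel_level_sigma: bool = False
) -> VOIStats:
    """Assemble the Eq.-style count statistics for one sphere diameter.

    ``sigma_bg`` is the SD of the 12 background-VOI means by default; with
    ``voxel_level_sigma=True`` it is the SD over all voxels pooled from the
    12 background VOIs (the two readings of the published wording).
    """
    sphere = voi_stats(volume, vois.spheres[diameter])
    bg_means = [voi_stats(volume, m).mean for m in vois.background_spheres[diameter]]
    if voxel_level_sigma:
        pooled = np.concatenate(
            [np.asarray(volume)[m] for m in vois.background_spheres[diameter]]
        )
        sd_bg = float(pooled.std(ddof=1))
    else:
        sd_bg = float(np.std(bg_means, ddof=1))
    big = np.concatenate([np.asarray(volume)[m] for m in vois.background_cylinders])
    lung = voi_stats(volume, vois.lung)
    return VOIStats(
        mean_sphere=sphere.mean,
        mean_bg=float(np.mean(bg_means)),
        sd_bg=sd_bg,
        mean_bg_large=float(big.mean()),
        sd_bg_large=float(big.std(ddof=1)),
        mean_lung=lung.mean,
    )


def calibrate_on_cylinder(
    volume: np.ndarray,
    voi_mask: np.ndarray,
    grid: VoxelGrid,
    acq_time_s: float,
    conc_true_mbq_ml: float,
) -> CalibrationResult:
    """Calibration factor from a uniform-cylinder acquisition and a large VOI."""
    stats = voi_stats(volume, voi_mask)
    v_voi_ml = stats.n_voxels * grid.voxel_volume_ml
    return calibration_factor(stats.total, v_voi_ml, acq_time_s, conc_true_mbq_ml)


@dataclass(frozen=True)
class IQReport:
    """Full image-quality report for one phantom acquisition."""

    nuclide: str
    collimator: str
    window: str
    true_ratio: float | None
    scatter_corrected: bool
    crc_pct: dict[float, float | None]
    cnr: dict[float, float | None]
    rc: dict[float, float | None]
    fwhm_mm: dict[float, float | None]
    fwhm_converged: dict[float, bool]
    cv_bg_pct: float | None
    lung_error_pct: float | None
    rc_bg: float | None
    voi_stats: dict[float, VOIStats] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "nuclide": self.nuclide,
            "collimator": self.collimator,
            "window": self.window,
            "true_ratio": self.true_ratio,
            "scatter_corrected": self.scatter_corrected,
            "crc_pct": {str(k): v for k, v in self.crc_pct.items()},
            "cnr": {str(k): v for k, v in self.cnr.items()},
            "rc": {str(k): v for k, v in self.rc.items()},
            "fwhm_mm": {str(k): v for k, v in self.fwhm_mm.items()},
            "fwhm_converged": {str(k): v for k, v in self.fwhm_converged.items()},
            "cv_bg_pct": self.cv_bg_pct,
            "lung_error_pct": self.lung_error_pct,
            "rc_bg": self.rc_bg,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_table(self) -> pd.DataFrame:
        rows = []
        for d in self.crc_pct:
            rows.append(("crc_pct", d, self.crc_pct[d]))
            rows.append(("cnr", d, self.cnr[d]))
            rows.append(("rc", d, self.rc[d]))
            rows.append(("fwhm_mm", d, self.fwhm_mm[d]))
        rows.append(("cv_bg_pct", np.nan, self.cv_bg_pct))
        rows.append(("lung_error_pct", np.nan, self.lung_error_pct))
        rows.append(("rc_bg", np.nan, self.rc_bg))
        return pd.DataFrame(rows, columns=["metric", "sphere_diameter_mm", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False)


def analyze_iq(
    images: dict[str, np.ndarray],
    vois: VOISet,
    spec: PhantomSpec,
    cal: CalibrationResult | None,
    acq_time_s: float,
    *,
    window_set=None,
    nuclide: str = "",
    collimator: str = "",
    window: str = "",
    voxel_level_sigma: bool = False,
    fit_fwhm: bool = True,
) -> IQReport:
    """Run the full image-quality analysis on a per-window image set.

    If scatter windows are present (and a window set is given), the volume
    is TEW-corrected per voxel first; otherwise the report is flagged
    uncorrected.  CRC and ΔN_Lung are omitted (None) for background-free
    fills.  RC values require a calibration result.
    """
    if "photopeak" not in images:
        raise ValueError("image set must contain a 'photopeak' volume")
    volume = np.asarray(images["photopeak"], dtype=float)
    scatter_corrected = False
    if window_set is not None and "lower_scatter" in images and "upper_scatter" in images:
        volume = tew_correct_volumes(
            volume, images["lower_scatter"], images["upper_scatter"], window_set
        )
        scatter_corrected = True
    missing = [
        name
        for name, m in [("spheres", vois.spheres), ("background_spheres", vois.background_spheres)]
        if not m
    ]
    if not vois.background_cylinders:
        missing.append("background_cylinders")
    if vois.lung is None:
        missing.append("lung")
    if missing:
        raise ValueError(f"VOI set is missing: {', '.join(missing)}")

    ratio = spec.contrast_ratio
    has_background = spec.background_kbq_ml > 0
    grid = vois.grid
    crc_d: dict[float, float | None] = {}
    cnr_d: dict[float, float | None] = {}
    rc_d: dict[float, float | None] = {}
    fwhm_d: dict[float, float | None] = {}
    fwhm_ok: dict[float, bool] = {}
    stats_d: dict[float, VOIStats] = {}
    conc_sphere_true = spec.sphere_kbq_ml / 1000.0  # MBq/ml
    for d in spec.sphere_diameters_mm:
        stats = compute_voi_stats(volume, vois, d, voxel_level_sigma=voxel_level_sigma)
        stats_d[d] = stats
        crc_d[d] = crc(stats, ratio) if (has_background and ratio and ratio > 1) else None
        cnr_d[d] = cnr(stats) if stats.sd_bg > 0 else None
        if cal is not None and conc_sphere_true > 0:
            conc_meas = counts_to_concentration(
                stats.mean_sphere, cal, acq_time_s, grid.voxel_volume_ml
            )
            rc_d[d] = recovery_coefficient(conc_meas, conc_sphere_true)
        else:
            rc_d[d] = None
        if fit_fwhm:
            res = fwhm_from_sphere(volume, grid, vois.sphere_centers[d], d / 2.0)
            fwhm_d[d] = res.fwhm_mm
            fwhm_ok[d] = res.converged
        else:
            fwhm_d[d] = None
            fwhm_ok[d] = False

    any_stats = stats_d[spec.sphere_diameters_mm[0]]
    cv_val = cv_bg(any_stats) if any_stats.mean_bg_large > 0 else None
    lung_val = lung_error(any_stats) if has_background and any_stats.mean_bg_large > 0 else None
    rc_bg_val = None
    if cal is not None and has_background:
        conc_bg_meas = counts_to_concentration(
            any_stats.mean_bg_large, cal, acq_time_s, grid.voxel_volume_ml
        )
        rc_bg_val = recovery_coefficient(conc_bg_meas, spec.background_kbq_ml / 1000.0)
    return IQReport(
        nuclide=nuclide,
        collimator=collimator,
        window=window,
        true_ratio=ratio,
        scatter_corrected=scatter_corrected,
        crc_pct=crc_d,
        cnr=cnr_d,
        rc=rc_d,
        fwhm_mm=fwhm_d,
        fwhm_converged=fwhm_ok,
        cv_bg_pct=cv_val,
        lung_error_pct=lung_val,
        rc_bg=rc_bg_val,
        voi_stats=stats_d,
    )
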