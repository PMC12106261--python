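"""Paralyzable dead-time model: sensitivity, fitting and loss inversion.

A paralyzable gamma camera observes the count rate

    C(A) = alpha * A * exp(-tau * alpha * A)

where ``A`` is the activity in the field of view (MBq), ``alpha`` the linear
detector performance (cps/MBq) and ``tau`` the detector dead time (s).  The
curve rises, peaks at ``A_peak = 1/(tau*alpha)`` and then falls: at high
activity more events paralyze the detector than are recorded.  For Pb-212
the high-energy daughter photons (e.g. 2.6 MeV from Tl-208) make these
losses severe even at therapy-scale activities, so the fitted model and its
inversions (activity at a given fractional loss, activity at the peak) are
the quantities of clinical interest.

The fit is parameterized in ``(alpha, tau_alpha)`` where
``tau_alpha = tau * alpha`` (1/MBq): the model depends on ``tau`` only
through this product, and the product is far less correlated with ``alpha``
than ``tau`` itself.  ``tau`` is reported as the derived ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CountRatePoint",
    "CountRateSeries",
    "PDMFit",
    "SensitivityResult",
    "FitError",
    "compute_sensitivity",
    "pdm_count_rate",
    "fit_pdm",
    "activity_at_loss",
    "activity_at_peak",
]


class FitError(RuntimeError):
    """Nonlinear fit failed or had too few usable points."""


@dataclass(frozen=True)
class CountRatePoint:
    """One count-rate measurement: activity at scan time, counts, duration."""

    activity_mbq: float
    counts: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.activity_mbq < 0:
            raise ValueError("activity must be non-negative")
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        if self.counts < 0:
            raise ValueError("counts must be non-negative")

    @property
    def count_rate_cps(self) -> float:
        return self.counts / self.duration_s


@dataclass(frozen=True)
class CountRateSeries:
    """Ordered count-rate measurements for one (nuclide, collimator, window)."""

    points: tuple[CountRatePoint, ...]
    nuclide: str = ""
    collimator: str = ""
    window: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if any(p.activity_mbq <= 0 for p in self.points):
            raise ValueError("series activities must be strictly positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def activities(self) -> np.ndarray:
        return np.array([p.activity_mbq for p in self.points])

    @property
    def count_rates(self) -> np.ndarray:
        return np.array([p.count_rate_cps for p in self.points])

    @classmethod
    def from_csv(cls, path: str | Path, **labels: str) -> "CountRateSeries":
        """Read a series from CSV columns (activity_MBq, counts, duration_s)."""
        df = pd.read_csv(path)
        required = {"activity_MBq", "counts", "duration_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"count-rate CSV missing columns: {sorted(missing)}")
        points = []
        for i, row in df.iterrows():
            try:
                points.append(
                    CountRatePoint(
                        float(row["activity_MBq"]),
                        float(row["counts"]),
                        float(row["duration_s"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed count-rate CSV at row {i}: {exc}") from exc
        return cls(tuple(points), **labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "activity_MBq": [p.activity_mbq for p in self.points],
                "counts": [p.counts for p in self.points],
                "duration_s": [p.duration_s for p in self.points],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SensitivityResult:
    sensitivity_cps_per_mbq: float
    window: str = ""
    collimator: str = ""

    def __post_init__(self) -> None:
        if self.sensitivity_cps_per_mbq < 0:
            raise ValueError("sensitivity must be non-negative")


@dataclass(frozen=True)
class PDMFit:
    """Fitted paralyzable-model parameters.

    ``tau_alpha`` (1/MBq) is the natural fitted scale; the dead time in
    seconds is the derived ratio ``tau_s = tau_alpha / alpha``.
    """

    alpha_cps_per_mbq: float
    tau_alpha_per_mbq: float
    excluded_points: tuple[int, ...] = field(default_factory=tuple)
    residual_norm_cps: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha_cps_per_mbq > 0:
            raise ValueError("alpha must be positive")
        if self.tau_alpha_per_mbq < 0:
            raise ValueError("tau_alpha must be non-negative")
        object.__setattr__(self, "excluded_points", tuple(self.excluded_points))

    @property
    def tau_s(self) -> float:
        return self.tau_alpha_per_mbq / self.alpha_cps_per_mbq

    def to_dict(self) -> dict:
        return {
            "alpha_cps_per_mbq": self.alpha_cps_per_mbq,
            "tau_alpha_per_mbq": self.tau_alpha_per_mbq,
            "tau_s": self.tau_s,
            "excluded_points": list(self.excluded_points),
            "residual_norm_cps": self.residual_norm_cps,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_sensitivity(
    counts: float, duration_s: float, activity_mbq: float, *, window: str = "", collimator: str = ""
) -> SensitivityResult:
    """Planar sensitivity: total FOV counts / (acquisition time × activity)."""
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    if not activity_mbq > 0:
        raise ValueError("activity must be positive")
    return SensitivityResult(
        counts / (duration_s * activity_mbq), window=window, collimator=collimator
    )


def pdm_count_rate(
    alpha_cps_per_mbq: float, tau_alpha_per_mbq: float, activity_mbq
) -> np.ndarray | float:
    """Paralyzable-model count rate ``alpha * A * exp(-tau_alpha * A)`` (cps).

    Accepts scalar or array activity.  With ``tau_alpha = 0`` this is the
    ideal linear response.
    """
    a = np.asarray(activity_mbq, dtype=float)
    if np.any(a < 0):
        raise ValueError("activity must be non-negative")
    out = alpha_cps_per_mbq * a * np.exp(-tau_alpha_per_mbq * a)
    return float(out) if np.isscalar(activity_mbq) else out


def _post_peak_indices(rates: np.ndarray) -> tuple[int, ...]:
    """Indices strictly after the global count-rate maximum.

    The exclusion rule for fitting: measurements past the observed peak are
    in the falling, paralyzed branch and are not fitted.  Noise-induced dips
    *before* the global maximum are retained.
    """
    argmax = int(np.argmax(rates))
    return tuple(range(argmax + 1, len(rates)))


def fit_pdm(series: CountRateSeries, *, poisson_weights: bool = False) -> PDMFit:
    """Fit the paralyzable model to a count-rate series.

    Points after the global observed count-rate maximum are excluded (the
    detector is past its peak there) and recorded in ``excluded_points``.
    ``alpha`` is initialized from the low-activity slope and ``tau_alpha``
    from 1/max(A).  The least squares is unweighted on count rate by
    default; ``poisson_weights=True`` weights each point by its Poisson
    standard error sqrt(counts)/duration.
    """
    if len(series) < 4:
        raise FitError(f"need at least 4 points, got {len(series)}")
    a = series.activities
    c = series.count_rates
    order = np.argsort(a)
    a_sorted, c_sorted = a[order], c[order]
    excluded_sorted = _post_peak_indices(c_sorted)
    keep = np.setdiff1d(np.arange(len(a_sorted)), excluded_sorted)
    if keep.size < 4:
        raise FitError(
            f"only {keep.size} points remain before the count-rate peak; need >= 4"
        )
    a_fit, c_fit = a_sorted[keep], c_sorted[keep]

    # initialization: slope of the lowest-activity third, 1/max(A) dead-time scale
    n_lo = max(2, len(a_fit) // 3)
    alpha0 = float(np.mean(c_fit[:n_lo] / a_fit[:n_lo]))
    p0 = (alpha0, 1.0 / float(a_fit.max()))

    sigma = None
    if poisson_weights:
        counts_fit = np.array([series.points[i].counts for i in order[keep]])
        durations = np.array([series.points[i].duration_s for i in order[keep]])
        sigma = np.sqrt(np.maximum(counts_fit, 1.0)) / durations

    try:
        popt, _ = curve_fit(
            lambda a, alpha, tau_alpha: pdm_count_rate(alpha, tau_alpha, a),
            a_fit,
            c_fit,
            p0=p0,
            sigma=sigma,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"paralyzable-model fit did not converge: {exc}") from exc
    alpha, tau_alpha = (float(v) for v in popt)
    resid = c_fit - pdm_count_rate(alpha, tau_alpha, a_fit)
    # excluded indices reported in the caller's original point order
    excluded_original = tuple(sorted(int(order[i]) for i in excluded_sorted))
    return PDMFit(
        alpha_cps_per_mbq=alpha,
        tau_alpha_per_mbq=tau_alpha,
        excluded_points=excluded_original,
        residual_norm_cps=float(np.linalg.norm(resid)),
    )


def activity_at_loss(fit: PDMFit, loss_fraction: float) -> float:
    """Activity (MBq) at which the fractional count loss reaches ``loss_fraction``.

    The loss at activity A is L(A) = 1 - exp(-tau_alpha*A), so
    ``A = -ln(1 - loss_fraction) / tau_alpha``.  With no dead time the
    threshold is infinite.
    """
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss fraction must be in [0, 1)")
    if fit.tau_alpha_per_mbq == 0:
        return math.inf if loss_fraction > 0 else 0.0
    return -math.log1p(-loss_fraction) / fit.tau_alpha_per_mbq


def activity_at_peak(fit: PDMFit) -> float:
    """Activity (MBq) at the count-rate maximum: ``1 / tau_alpha`` (dC/dA = 0)."""
    if fit.tau_alpha_per_mbq == 0:
        return math.inf
    return 1.0 / fit.tau_alpha_per_mbq
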