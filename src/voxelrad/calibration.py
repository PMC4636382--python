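"""Characterisation fitters: response function, variance decomposition,
ROI statistics, SNR and CNR.

These reusable fitters mirror the measurement procedures used to
characterise a real detector: exposing flat fields over a dose range,
reading mean and standard deviation in a central ROI, fitting the
logarithmic response ``PV = b + a ln(K)`` and decomposing the flat-field
variance into ``sigma^2 = alpha*D + beta*D^2 + gamma``.  Run against the
simulator's own output they close the loop: the recovered coefficients
should match the generator inputs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "RoiStats",
    "VarianceFit",
    "fit_response",
    "fit_variance",
    "roi_stats",
    "snr",
    "cnr",
    "central_roi",
    "variance_closed_loop",
    "DEFAULT_DOSE_SERIES_UGY",
    "export_series_csv",
    "plot_variance_fit",
]

#: default flat-field dose levels for the variance closed loop, uGy —
#: ten levels spanning the 0.1-20 uGy range used for detector noise
#: characterisation (two decades, log-spaced).
DEFAULT_DOSE_SERIES_UGY = tuple(
    float(x) for x in np.geomspace(0.1, 20.0, 10).round(4)
)


@dataclass(frozen=True)
class RoiStats:
    """Mean / standard deviation of a rectangular region of interest."""

    mean: float
    sd: float
    n: int
    bounds: tuple[int, int, int, int]  # (row0, col0, rows, cols)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("ROI must contain at least 2 pixels")


@dataclass(frozen=True)
class VarianceFit:
    """Result of the three-component variance decomposition."""

    alpha: float
    beta: float
    gamma: float
    alpha_se: float
    beta_se: float
    gamma_se: float
    residual_rms: float

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.alpha * d + self.beta * d * d + self.gamma


def fit_response(kerma_series, pv_series) -> tuple[float, float, float]:
    """Least-squares fit of PV on ln(K); returns (a, b, R^2)."""
    k = np.asarray(kerma_series, dtype=float)
    pv = np.asarray(pv_series, dtype=float)
    if k.size < 2 or k.size != pv.size:
        raise ValueError("need >= 2 matched (kerma, PV) points")
    if np.any(k <= 0):
        raise ValueError("kerma values must be positive")
    x = np.log(k)
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: all kerma values equal")
    a, b = np.polyfit(x, pv, 1)
    resid = pv - (b + a * x)
    ss_tot = float(np.sum((pv - pv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(a), float(b), r2


def fit_variance(dose_series, variance_series) -> VarianceFit:
    """Non-negative least squares fit of ``sigma^2 = alpha*D + beta*D^2 + gamma``.

    The non-negativity constraint enforces the physical signs of the three
    noise components without any iterative tuning.  Standard errors come
    from the unconstrained normal equations evaluated at the solution (an
    approximation when a constraint is active).
    """
    d = np.asarray(dose_series, dtype=float)
    v = np.asarray(variance_series, dtype=float)
    if d.size < 3 or d.size != v.size:
        raise ValueError("need >= 3 matched (dose, variance) points")
    if np.any(v < 0):
        raise ValueError("variances must be non-negative")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    X = np.column_stack([d, d * d, np.ones_like(d)])
    coef, rnorm = nnls(X, v)
    resid = v - X @ coef
    dof = max(d.size - 3, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(X.T @ X)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    return VarianceFit(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        gamma=float(coef[2]),
        alpha_se=float(ses[0]),
        beta_se=float(ses[1]),
        gamma_se=float(ses[2]),
        residual_rms=math.sqrt(float(resid @ resid) / d.size),
    )


def roi_stats(image: np.ndarray, bounds: tuple[int, int, int, int]) -> RoiStats:
    """Mean and SD of the ROI ``(row0, col0, rows, cols)`` of a 2-D image."""
    arr = getattr(image, "kerma_uGy", image)
    arr = np.asarray(arr)
    r0, c0, nr, nc = bounds
    if r0 < 0 or c0 < 0 or r0 + nr > arr.shape[0] or c0 + nc > arr.shape[1]:
        raise ValueError(f"ROI {bounds} outside image {arr.shape}")
    roi = arr[r0 : r0 + nr, c0 : c0 + nc]
    return RoiStats(float(roi.mean()), float(roi.std(ddof=1)), roi.size, bounds)


def central_roi(image: np.ndarray, size_mm: float, pitch_mm: float) -> RoiStats:
    """Square ROI of physical side ``size_mm`` centred in the image."""
    arr = getattr(image, "kerma_uGy", image)
    arr = np.asarray(arr)
    n = max(int(round(size_mm / pitch_mm)), 2)
    n = min(n, *arr.shape)
    r0 = (arr.shape[0] - n) // 2
    c0 = (arr.shape[1] - n) // 2
    return roi_stats(arr, (r0, c0, n, n))


def snr(stats: RoiStats) -> float:
    """Signal-to-noise ratio, ROI mean / ROI sd; infinite for sd = 0."""
    if stats.sd == 0:
        return math.inf
    return stats.mean / stats.sd


def cnr(stats_a: RoiStats, stats_b: RoiStats) -> float:
    """Contrast-to-noise ratio with a pooled (quadrature-mean) denominator.

    ``|mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2) / 2)`` — symmetric in its
    arguments; infinite when both ROIs are noiseless.
    """
    pooled = math.sqrt((stats_a.sd**2 + stats_b.sd**2) / 2.0)
    contrast = abs(stats_a.mean - stats_b.mean)
    if pooled == 0:
        return math.inf if contrast > 0 else 0.0
    return contrast / pooled


def variance_closed_loop(
    det,
    kvp: float,
    doses=DEFAULT_DOSE_SERIES_UGY,
    roi_size_mm: float = 20.0,
    global_seed: int = 0,
) -> tuple[VarianceFit, tuple[float, float, float], list[float]]:
    """Simulate flat fields, measure ROI variance, refit the noise model.

    For each dose level a homogeneous exposure is simulated with the
    detector's noise coefficients at ``kvp``, the variance of a central
    square ROI (side ``roi_size_mm``) is measured on the dose image, and the
    three-component model is refit.  Returns (fit, input coefficients,
    measured variances).  Recovered alpha/beta matching the inputs is the
    central self-consistency check of the noise chain.
    """
    from .pipeline import simulate_flat_field

    n = max(int(round(roi_size_mm / det.pixel_pitch_mm)), 8)
    variances = []
    for i, d in enumerate(doses):
        img = simulate_flat_field(d, n, n, det, kvp, global_seed, image_id=i)
        variances.append(central_roi(img, roi_size_mm, det.pixel_pitch_mm).sd ** 2)
    fit = fit_variance(list(doses), variances)
    return fit, det.noise_coeffs(kvp), variances


def export_series_csv(path, dose_series, value_series, header=("dose_uGy", "value")):
    """Write a calibration series as a two-column CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for d, v in zip(dose_series, value_series):
            w.writerow([f"{d:.10g}", f"{v:.10g}"])


def plot_variance_fit(path, dose_series, variance_series, fit: VarianceFit) -> None:
    """Variance-vs-kerma plot with the fitted decomposition, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = np.asarray(dose_series, float)
    grid = np.geomspace(d.min(), d.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(d, variance_series, "o", label="measured")
    ax.loglog(grid, fit.predict(grid), "-", label="fit")
    ax.set_xlabel("incident air kerma (uGy)")
    ax.set_ylabel("variance (uGy$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
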