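"""Empirical scatter and antiscatter-grid modelling on the dose image.

Scatter is modelled as an energy-dependent, normalised Gaussian blur of the
primary dose image scaled by a scatter-to-primary coefficient,

    S = c_s(E) * G_sigma(P)

with ``sigma`` defined on the detector plane in mm and converted to pixels
through the detector pitch.  The antiscatter grid transmits primary and
scatter with separate factors,

    final = f_P(E) * P + f_S(E) * S     (grid in)
    final = P + S                        (grid out)

Convolution uses mirror padding so the border carries no dark-edge artefact
(which would corrupt edge-profile sigma estimation).

The module also provides the two empirical calibration estimators: Gaussian
sigma from the penumbra of an edge profile, and the scatter grid factor
``f_S`` from paired with/without-grid exposures with the primary
contribution subtracted.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize, special

from .dosimetry import DoseImage

__all__ = [
    "scatter_dose",
    "apply_grid",
    "estimate_sigma_from_edge",
    "estimate_scatter_fraction",
]


def _as_params(params, beam_label):
    """Accept a DetectorModel-like object or an explicit (sigma, c_s) pair."""
    sigma = params.sigma_mm(beam_label)
    c_s = params.c_s(beam_label)
    if sigma < 0 or c_s < 0:
        raise ValueError("sigma and c_s must be non-negative")
    return sigma, c_s


def scatter_dose(primary: DoseImage, params, beam_label: float) -> DoseImage:
    """Scatter dose image: ``c_s * G_sigma(primary)``.

    ``params`` is any object exposing ``sigma_mm(kvp)`` and ``c_s(kvp)``
    (a :class:`~voxelrad.detector.DetectorModel` in practice).  The kernel
    is sum-normalised, so in any flat interior region scatter/primary equals
    ``c_s``; with ``sigma -> 0`` it degenerates to ``c_s * primary``.
    """
    sigma_mm, c_s = _as_params(params, beam_label)
    sigma_px = sigma_mm / primary.pitch_mm
    if sigma_px == 0:
        blurred = primary.kerma_uGy.copy()
    else:
        blurred = ndimage.gaussian_filter(primary.kerma_uGy, sigma_px, mode="mirror")
    return DoseImage(c_s * blurred, primary.pitch_mm, dict(primary.meta))


def apply_grid(
    primary: DoseImage,
    scatter: DoseImage,
    params,
    beam_label: float,
    grid_present: bool = True,
) -> DoseImage:
    """Combine primary and scatter, attenuated by the grid if present."""
    if primary.shape != scatter.shape:
        raise ValueError(
            f"primary {primary.shape} and scatter {scatter.shape} shapes differ"
        )
    if grid_present:
        f_p, f_s = params.f_p(beam_label), params.f_s(beam_label)
        if not (0 < f_p <= 1 and 0 < f_s <= 1):
            raise ValueError("grid factors must lie in (0, 1]")
        out = f_p * primary.kerma_uGy + f_s * scatter.kerma_uGy
    else:
        out = primary.kerma_uGy + scatter.kerma_uGy
    meta = dict(primary.meta)
    meta["grid"] = bool(grid_present)
    return DoseImage(out, primary.pitch_mm, meta)


def _erf_edge(x, lo, hi, x0, sigma):
    return lo + (hi - lo) * 0.5 * (1.0 + special.erf((x - x0) / (np.sqrt(2) * sigma)))


def estimate_sigma_from_edge(
    edge_image: DoseImage, min_contrast: float = 0.05
) -> float:
    """Gaussian sigma (mm) from the penumbra of a straight vertical edge.

    The rows of the image are averaged into one edge profile, which is fit to
    a plateau-erf-plateau model; the fitted transition width is the blur
    sigma on the detector plane.  Raises if the plateau contrast is below
    ``min_contrast`` (no detectable edge).
    """
    profile = edge_image.kerma_uGy.mean(axis=0)
    n = profile.size
    lo0, hi0 = float(profile.min()), float(profile.max())
    if hi0 <= 0 or (hi0 - lo0) / hi0 < min_contrast:
        raise ValueError("no detectable edge: plateau contrast below threshold")
    x = np.arange(n, dtype=float)
    x0_0 = float(np.argmax(np.abs(np.gradient(profile))))
    # fit in pixel units; orientation (rising/falling) handled by lo/hi signs
    rising = profile[-1] >= profile[0]
    p0 = (lo0 if rising else hi0, hi0 if rising else lo0, x0_0, max(n / 50.0, 0.5))
    popt, _ = optimize.curve_fit(
        _erf_edge, x, profile, p0=p0, maxfev=20000
    )
    sigma_px = abs(float(popt[3]))
    return sigma_px * edge_image.pitch_mm


def estimate_scatter_fraction(
    with_grid: DoseImage,
    without_grid: DoseImage,
    roi: tuple[int, int, int, int],
    primary_roi_mean: float,
    f_p: float = 1.0,
) -> float:
    """Grid scatter transmission f_S from paired exposures.

    ``roi`` is (row0, col0, rows, cols) and must lie outside the projected
    phantom, where the signal is free-air primary plus scatter spilling over
    the edge.  ``primary_roi_mean`` is the predicted free-air primary dose in
    that ROI *without* grid; with the grid the primary contribution is
    ``f_p * primary_roi_mean``.  Returns the ratio of the residual scatter
    with / without grid.
    """
    r0, c0, nr, nc = roi
    if nr < 1 or nc < 1:
        raise ValueError("ROI must contain at least one pixel")
    sl = (slice(r0, r0 + nr), slice(c0, c0 + nc))
    s_with = float(with_grid.kerma_uGy[sl].mean()) - f_p * primary_roi_mean
    s_without = float(without_grid.kerma_uGy[sl].mean()) - primary_roi_mean
    if s_without <= 0:
        raise ValueError("no scatter detected: residual after primary subtraction <= 0")
    return max(s_with, 0.0) / s_without
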