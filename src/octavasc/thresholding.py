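"""Binarization algorithms used per anatomical layer.

The study's per-layer assignment is:

* superficial retinal plexus -> Li minimum cross-entropy threshold,
* deep retinal plexus        -> Otsu between-class-variance threshold,
* choriocapillaris           -> Phansalkar local adaptive threshold.

Li and Otsu are global, histogram-based thresholds; Phansalkar computes a
per-pixel threshold from the local windowed mean and standard deviation,

    t(x) = mu_w(x) * (1 + p * exp(-q * mu_w(x)) + k * (sigma_w(x) / r - 1)),

which is designed for low-contrast images such as choriocapillaris flow maps.
For bright structures foreground is defined by strict ``pixel > threshold``;
``dark_fg`` polarity (used for flow voids) keeps ``pixel <= threshold``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .exceptions import ConvergenceError, LayerError, NoContrastError, OctavascError
from .images import BinaryMap, EnFaceAngiogram, as_pixels

#: Published constants of the Phansalkar method; the window radius is set to
#: about one capillary lobule (90 um = 15 px at 6 um/px).
PHANSALKAR_DEFAULTS = {"radius_px": 15, "k": 0.25, "r": 0.5, "p": 2.0, "q": 10.0}


def otsu_threshold(image, n_bins: int = 256) -> float:
    """Global threshold maximizing between-class variance.

    The intensity range is divided into ``n_bins`` histogram levels; the
    returned threshold is the bin center maximizing the weighted between-class
    variance ``w0 * w1 * (mu0 - mu1)**2``. Foreground is ``pixels > t``.

    Raises
    ------
    NoContrastError
        If the image is constant.
    """
    px = as_pixels(image).ravel().astype(float)
    lo, hi = px.min(), px.max()
    if lo == hi:
        raise NoContrastError("no contrast: image is constant")
    hist, edges = np.histogram(px, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(float)

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * centers)
    total = s0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (total - s0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # split after the last bin is degenerate (empty foreground)
    between[-1] = -np.inf
    return float(centers[int(np.argmax(between))])


def _class_means(px: np.ndarray, t: float) -> tuple[float, float]:
    below = px[px <= t]
    above = px[px > t]
    eps = 1e-12
    mb = float(below.mean()) if below.size else eps
    mf = float(above.mean()) if above.size else eps
    return max(mb, eps), max(mf, eps)


def _cross_entropy(px: np.ndarray, t: float) -> float:
    """Li's cross-entropy objective (up to an additive constant)."""
    below = px[px <= t]
    above = px[px > t]
    if below.size == 0 or above.size == 0:
        return np.inf
    eps = 1e-12
    return -(below.sum() * np.log(max(below.mean(), eps))
             + above.sum() * np.log(max(above.mean(), eps)))


def li_threshold(image, tol: float = 1e-6, max_iter: int = 100) -> float:
    """Li & Tam minimum cross-entropy threshold.

    Iterates ``t' = (mu_b - mu_f) / (ln mu_b - ln mu_f)`` where ``mu_b`` and
    ``mu_f`` are the mean intensities at or below / strictly above the current
    iterate, until ``|t' - t| < tol``. Because the discrete objective is
    piecewise constant between observed intensities, the continuous fixed
    point is then polished by a local search over the neighbouring inter-value
    cut points so the returned threshold attains the cross-entropy minimum.
    Intensities must be non-negative (guaranteed for normalized angiograms).

    Raises
    ------
    NoContrastError
        If the image is constant.
    ConvergenceError
        If the fixed point is not reached within ``max_iter`` iterations;
        the exception carries the last iterate.
    """
    px = as_pixels(image).ravel().astype(float)
    lo, hi = px.min(), px.max()
    if lo == hi:
        raise NoContrastError("no contrast: image is constant")
    t = float(px.mean())
    converged = False
    for _ in range(max_iter):
        mb, mf = _class_means(px, t)
        if np.isclose(mb, mf):
            converged = True
            break
        t_new = (mb - mf) / (np.log(mb) - np.log(mf))
        if abs(t_new - t) < tol:
            t = float(t_new)
            converged = True
            break
        t = float(t_new)
    if not converged:
        raise ConvergenceError(
            f"Li threshold did not converge in {max_iter} iterations (last iterate {t:.6g})",
            last_iterate=t,
        )
    # local polish over the discrete plateaus around the fixed point
    delta = 0.02 * (hi - lo)
    uniq = np.unique(px[(px >= t - delta) & (px <= t + delta)])
    if uniq.size >= 2:
        candidates = np.concatenate([[t], 0.5 * (uniq[:-1] + uniq[1:])])
        values = [_cross_entropy(px, c) for c in candidates]
        t = float(candidates[int(np.argmin(values))])
    return t


def phansalkar_binarize(
    image,
    radius_px: int = PHANSALKAR_DEFAULTS["radius_px"],
    k: float = PHANSALKAR_DEFAULTS["k"],
    r: float = PHANSALKAR_DEFAULTS["r"],
    p: float = PHANSALKAR_DEFAULTS["p"],
    q: float = PHANSALKAR_DEFAULTS["q"],
    polarity: str = "bright_fg",
) -> BinaryMap:
    """Local adaptive binarization after Phansalkar.

    The windowed mean and population standard deviation are computed over a
    circular window of radius ``radius_px`` with mirror-padded borders; the
    per-pixel threshold follows the formula in the module docstring.
    ``bright_fg`` keeps ``pixel > t``; ``dark_fg`` keeps ``pixel <= t``.
    """
    px = as_pixels(image).astype(float)
    if radius_px < 1:
        raise OctavascError("radius_px must be >= 1")
    if radius_px > min(px.shape) // 2:
        raise OctavascError(
            f"window radius {radius_px} exceeds half the image side {min(px.shape) // 2}"
        )
    if polarity not in ("bright_fg", "dark_fg"):
        raise OctavascError(f"unknown polarity {polarity!r}")

    footprint = disk(radius_px).astype(float)
    weights = footprint / footprint.sum()
    mean = ndimage.correlate(px, weights, mode="mirror")
    mean_sq = ndimage.correlate(px * px, weights, mode="mirror")
    sigma = np.sqrt(np.clip(mean_sq - mean * mean, 0.0, None))
    thresh = mean * (1.0 + p * np.exp(-q * mean) + k * (sigma / r - 1.0))
    fg = px > thresh if polarity == "bright_fg" else px <= thresh
    return BinaryMap(
        pixels=fg,
        provenance={
            "algorithm": "phansalkar",
            "radius_px": radius_px,
            "k": k,
            "r": r,
            "p": p,
            "q": q,
            "polarity": polarity,
        },
    )


def binarize_layer(image: EnFaceAngiogram, phansalkar_params: dict | None = None) -> BinaryMap:
    """Binarize an angiogram with the algorithm assigned to its layer.

    Superficial -> Li, deep -> Otsu (both with strict ``>`` foreground),
    choriocapillaris -> Phansalkar with bright foreground (flow map).
    """
    if not isinstance(image, EnFaceAngiogram):
        raise OctavascError("binarize_layer requires an EnFaceAngiogram with its layer set")
    if image.layer == "superficial":
        t = li_threshold(image)
        return BinaryMap(image.pixels > t, provenance={"algorithm": "li", "threshold": t})
    if image.layer == "deep":
        t = otsu_threshold(image)
        return BinaryMap(image.pixels > t, provenance={"algorithm": "otsu", "threshold": t})
    if image.layer == "choriocapillaris":
        params = dict(PHANSALKAR_DEFAULTS)
        params.update(phansalkar_params or {})
        return phansalkar_binarize(image, polarity="bright_fg", **params)
    raise LayerError(f"unknown layer {image.layer!r}")
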