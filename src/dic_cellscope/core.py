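"""Calibrated grayscale image model and the low-level raster operators.

Everything downstream (seeding, watershed segmentation, morphometry) is
composed from the primitives here: brightness normalization, subtractive
illumination correction, Sobel gradient magnitude, single- and two-threshold
Otsu on 256-bin histograms, and the exact Euclidean distance transform.

Conventions
-----------
* Intensities live in ``[0, 1]``; 8/16-bit files are mapped by division by
  the dtype maximum at load time (see :mod:`dic_cellscope.io`).
* Rasters are ``(rows, cols)`` with row 0 at the top; the shear direction
  ``theta`` (degrees) points along ``(cos t) * columns + (sin t) * rows``.
* Histograms use 256 equal-width bins over ``[0, 1]``; a threshold is a bin
  index ``t`` and "above threshold" means the pixel's bin index exceeds ``t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

MAGNIFICATIONS = ("10x", "20x", "40x")

#: Placeholder calibrations (micrometres per pixel) used when a manifest does
#: not supply one; real analyses should always calibrate explicitly.
DEFAULT_UM_PER_PX = {"10x": 1.0, "20x": 0.5, "40x": 0.25}

N_BINS = 256


class DegenerateImageWarning(UserWarning):
    """An operator received input without usable contrast."""


class DegenerateHistogramError(ValueError):
    """A histogram does not carry enough distinct mass for the request."""


class ParameterError(ValueError):
    """An operator parameter is outside its documented domain."""


@dataclass
class GrayImage:
    """Single-channel intensity raster with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of intensities in ``[0, 1]``.
    magnification : {"10x", "20x", "40x"}
        Objective magnification; drives method dispatch and area filters.
    um_per_px : float
        Micrometres per pixel (> 0).
    day : int, optional
        Culture day (>= 1) the image was acquired on.
    image_id : str
        Opaque identifier used for provenance in feature tables.
    """

    pixels: np.ndarray
    magnification: str = "10x"
    um_per_px: float = 1.0
    day: Optional[int] = None
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ParameterError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ParameterError("pixels contain non-finite values")
        if self.magnification not in MAGNIFICATIONS:
            raise ParameterError(f"unknown magnification {self.magnification!r}")
        if not self.um_per_px > 0:
            raise ParameterError("um_per_px must be > 0")
        if self.day is not None and self.day < 1:
            raise ParameterError("day must be >= 1")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same metadata, new raster."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass
class BinaryMask:
    """2-D raster of {0, 1} with the same shape contract as GrayImage."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1))):
                raise ParameterError("mask values must be in {0, 1}")
            px = px.astype(bool)
        self.pixels = px


# ---------------------------------------------------------------------------
# intensity helpers


def normalize_brightness(img: GrayImage) -> GrayImage:
    """Affinely rescale intensities so min -> 0 and max -> 1.

    A constant raster has no contrast to stretch; it maps to all zeros and a
    :class:`DegenerateImageWarning` is emitted.
    """
    px = img.pixels
    lo = float(px.min())
    hi = float(px.max())
    if hi - lo <= 0.0:
        warnings.warn(
            "constant image: brightness normalization is degenerate",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


def correct_illumination(img: GrayImage, sigma_frac: float = 0.125) -> GrayImage:
    """Remove slowly varying scene lighting by subtractive high-pass filtering.

    The background estimate is a Gaussian blur with a large kernel
    (``sigma = sigma_frac * min(rows, cols)``); the residual is re-stretched
    to ``[0, 1]``.  Borders are handled by edge replication.

    Parameters
    ----------
    sigma_frac : float
        Blur scale as a fraction of the smaller image dimension,
        in ``(0, 0.5]``.  The default 0.125 removes shading varying on the
        scene scale while leaving cell-scale detail untouched.
    """
    if not 0.0 < sigma_frac <= 0.5:
        raise ParameterError("sigma_frac must be in (0, 0.5]")
    sigma = sigma_frac * min(img.shape)
    background = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="nearest")
    residual = img.pixels - background
    with warnings.catch_warnings():
        # a constant input has a constant residual; normalize flags it already
        warnings.simplefilter("always")
        return normalize_brightness(img.with_pixels(residual))


def sobel_magnitude(img: GrayImage) -> GrayImage:
    """Gradient magnitude of the 3x3 Sobel pair, rescaled to ``[0, 1]``.

    Borders are edge-replicated so flat borders do not produce spurious rims.
    """
    gx = ndimage.sobel(img.pixels, axis=1, mode="nearest")
    gy = ndimage.sobel(img.pixels, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = float(mag.max())
    if peak > 0.0:
        mag /= peak
    return img.with_pixels(mag)


def directional_derivative(arr: np.ndarray, theta_deg: float) -> np.ndarray:
    """Forward-difference derivative along the shear direction ``theta``.

    ``D_theta f = cos(t) * (f[i, j+1] - f[i, j]) + sin(t) * (f[i+1, j] - f[i, j])``
    with Neumann (replicated) boundaries, i.e. the difference is zero past the
    last column/row.  The same stencil drives the synthetic DIC render and the
    Feineigle reconstruction, so forward and inverse models are consistent.
    """
    arr = np.asarray(arr, dtype=np.float64)
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros_like(arr)
    out[:, :-1] += c * (arr[:, 1:] - arr[:, :-1])
    out[:-1, :] += s * (arr[1:, :] - arr[:-1, :])
    return out


# ---------------------------------------------------------------------------
# histograms and Otsu thresholding


def intensity_bins(values: np.ndarray) -> np.ndarray:
    """Map intensities in [0, 1] to bin indices 0..255."""
    return np.clip((np.asarray(values) * N_BINS).astype(np.int64), 0, N_BINS - 1)


def histogram256(values: np.ndarray) -> np.ndarray:
    """256-bin histogram of intensities over equal-width bins spanning [0, 1]."""
    return np.bincount(intensity_bins(values).ravel(), minlength=N_BINS)


def threshold_mask(values: np.ndarray, t: int) -> np.ndarray:
    """Boolean mask of pixels strictly above threshold bin ``t``."""
    return intensity_bins(values) > t


def otsu_threshold(counts: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the bin ``t`` maximizing the between-class variance of the split
    ``[0..t]`` vs ``[t+1..255]``; the smallest maximizer wins ties.  If all
    mass sits in one bin the split is meaningless: that bin is returned and a
    :class:`DegenerateImageWarning` is emitted.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    nonempty = np.flatnonzero(counts)
    if nonempty.size == 1:
        warnings.warn(
            "single-bin histogram: Otsu threshold is degenerate",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return int(nonempty[0])
    idx = np.arange(N_BINS)
    w = np.cumsum(counts)
    m = np.cumsum(counts * idx)
    w0 = w[:-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (m[-1] - m[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~((w0 > 0) & (w1 > 0))] = -np.inf
    return int(np.argmax(sigma_b))  # argmax -> first occurrence = smallest t


def two_threshold_otsu(counts: np.ndarray) -> tuple[int, int]:
    """Two-threshold (three-class) Otsu on a 256-bin histogram.

    Maximizes the three-class between-class variance over all pairs
    ``t1 < t2`` (classes ``[0..t1]``, ``[t1+1..t2]``, ``[t2+1..255]``),
    returning the lexicographically smallest maximizer.  Requires at least 3
    non-empty bins; otherwise a :class:`DegenerateHistogramError` is raised.

    Maximizing ``sum_c w_c * mu_c**2`` is equivalent to maximizing the
    between-class variance because the grand mean is fixed.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.count_nonzero(counts) < 3:
        raise DegenerateHistogramError(
            "two-threshold Otsu needs >= 3 non-empty bins"
        )
    idx = np.arange(N_BINS)
    W = np.cumsum(counts)
    M = np.cumsum(counts * idx)
    total, m_total = W[-1], M[-1]

    best = -np.inf
    best_pair = (0, 1)
    for t1 in range(N_BINS - 2):
        w0, m0 = W[t1], M[t1]
        t2 = np.arange(t1 + 1, N_BINS - 1)
        w1 = W[t2] - w0
        m1 = M[t2] - m0
        w2 = total - W[t2]
        m2 = m_total - M[t2]
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (
                np.where(w0 > 0, m0 * m0 / w0, 0.0)
                + np.where(w1 > 0, m1 * m1 / w1, 0.0)
                + np.where(w2 > 0, m2 * m2 / w2, 0.0)
            )
        j = int(np.argmax(score))
        if score[j] > best:  # strict: keeps lexicographically smallest pair
            best = float(score[j])
            best_pair = (t1, int(t2[j]))
    return best_pair


# ---------------------------------------------------------------------------
# distance transform


def distance_transform(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background (zero) pixel.

    Everything outside the raster counts as background, so an all-ones mask
    measures distance to the border ring rather than overflowing.
    """
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    padded = np.pad(px, 1, constant_values=False)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
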