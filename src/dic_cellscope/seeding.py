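"""Watershed marker generation.

Two seeding strategies are provided, matching the magnification regimes they
work best in:

* **Bespoke** (10x/20x): background removal from the Sobel-gradient Otsu
  support, then bright 8-connected blobs (brightness above Otsu) inside that
  support become markers.
* **Feineigle** (40x): a DIC image approximates the directional derivative of
  the specimen's optical density ``f``; regularized directional integration
  recovers ``f`` by Gauss-Seidel relaxation, and markers are extracted from
  the distance transform of the high-density class of a two-threshold Otsu
  split of the reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy import ndimage, sparse

from .core import (
    DegenerateHistogramError,
    DegenerateImageWarning,
    GrayImage,
    ParameterError,
    distance_transform,
    histogram256,
    normalize_brightness,
    otsu_threshold,
    sobel_magnitude,
    threshold_mask,
    two_threshold_otsu,
)

EIGHT = np.ones((3, 3), dtype=bool)

#: Pre-filter on marker blob size, per magnification.  Much smaller than the
#: post-segmentation area filter; it only suppresses seeding on noise specks.
DEFAULT_MIN_SEED_AREA = {"10x": 20, "20x": 50, "40x": 100}


@dataclass
class SeedMap:
    """Disjoint labeled markers feeding the watershed.

    ``labels`` is an integer raster: 0 = unmarked, 1..m = marker ids.  Each
    positive id forms exactly one 8-connected component and ids are
    consecutive.
    """

    labels: np.ndarray
    method: str = "bespoke"

    @property
    def n_seeds(self) -> int:
        return int(self.labels.max())


def validate_seed_map(seeds: SeedMap) -> None:
    """Raise AssertionError unless the SeedMap invariants hold."""
    _validate_label_raster(seeds.labels)


def _validate_label_raster(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    assert labels.ndim == 2
    assert np.issubdtype(labels.dtype, np.integer)
    n = int(labels.max())
    assert labels.min() >= 0
    ids = np.unique(labels)
    ids = ids[ids > 0]
    assert list(ids) == list(range(1, n + 1)), "ids must be consecutive 1..n"
    for rid, sl in zip(range(1, n + 1), ndimage.find_objects(labels, max_label=n)):
        assert sl is not None
        _, nc = ndimage.label(labels[sl] == rid, structure=EIGHT)
        assert nc == 1, f"id {rid} is not a single 8-connected component"


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map positive ids to 1..m preserving their order."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels]


def _label_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """8-connected components of ``mask`` at least ``min_area`` px, ids 1..m."""
    lab, n = ndimage.label(mask, structure=EIGHT)
    if n and min_area > 1:
        areas = np.bincount(lab.ravel(), minlength=n + 1)
        small = np.flatnonzero(areas[1:] + 0 < min_area) + 1
        if small.size:
            lab[np.isin(lab, small)] = 0
    return _relabel_consecutive(lab)


# ---------------------------------------------------------------------------
# Bespoke seeding (10x / 20x)


#: Smoothing scale (px) for the gradient-energy map behind the support mask.
GRAD_SMOOTH_SIGMA = 1.0


def _bespoke_support(img: GrayImage, smooth_sigma: float = GRAD_SMOOTH_SIGMA) -> np.ndarray:
    """Foreground support: gradient energy above Otsu, closed and hole-filled.

    The Sobel magnitude is smoothed before thresholding: pixel-level gradient
    magnitude of a noisy DIC image is heavy-tailed and Otsu on it is unstable
    (the threshold either drowns in amplified noise or cuts into the tail).
    Pooling the magnitude over a few pixels gives a bimodal local gradient
    energy that separates relief-bearing cells from flat background.
    """
    grad = sobel_magnitude(img).pixels
    if smooth_sigma > 0:
        grad = ndimage.gaussian_filter(grad, smooth_sigma, mode="nearest")
        peak = grad.max()
        if peak > 0:
            grad /= peak
    tg = otsu_threshold(histogram256(grad))
    # the Otsu cut sits well into the relief tail and clips the low-contrast
    # rim of every cell; taking 70% of it (still far above the noise floor)
    # extends the support out to the true footprint without inflating thin
    # cells the way an isotropic dilation would
    cut = 0.7 * (tg + 1) / 256.0
    # when cells cover little of the frame, Otsu can split the noise mode
    # itself and the cut lands inside it: enforce a robust noise floor from
    # the background statistics (left-sided MAD is insensitive to the cell
    # gradient tail)
    med = float(np.median(grad))
    left = grad[grad < med]
    left_mad = float(np.median(med - left)) if left.size else 0.0
    support = grad > max(cut, med + 4.0 * left_mad)
    support = ndimage.binary_closing(support, structure=EIGHT)
    return ndimage.binary_fill_holes(support)


def _bespoke(img: GrayImage, min_seed_area_px: int) -> tuple[SeedMap, np.ndarray]:
    empty = np.zeros(img.shape, dtype=np.int32)
    if img.pixels.max() - img.pixels.min() <= 0.0:
        warnings.warn(
            "constant image: no seeds can be extracted",
            DegenerateImageWarning,
            stacklevel=3,
        )
        return SeedMap(empty, method="bespoke"), np.zeros(img.shape, dtype=bool)
    support = _bespoke_support(img)
    if support.mean() > 0.95:
        # thresholding separated nothing: the gradient "support" is the whole
        # frame, which happens on signal-free (noise-only) images where Otsu
        # splits the noise distribution itself
        warnings.warn(
            "no distinguishable background: treating image as cell-free",
            DegenerateImageWarning,
            stacklevel=3,
        )
        return SeedMap(empty, method="bespoke"), np.zeros(img.shape, dtype=bool)
    bright = normalize_brightness(img)
    tb = otsu_threshold(histogram256(bright.pixels))
    seed_mask = threshold_mask(bright.pixels, tb) & support
    # a 3x3 opening suppresses percolating speckle on signal-free images while
    # leaving solid bright lobes of real cells intact; the subsequent small
    # closing re-joins fragments of a single lobe that noise broke apart
    # (fragments of one lobe sit a few px apart, distinct cells much further)
    seed_mask = ndimage.binary_opening(seed_mask, structure=EIGHT)
    yy, xx = np.mgrid[-3:4, -3:4]
    seed_mask = ndimage.binary_closing(seed_mask, structure=yy**2 + xx**2 <= 9)
    seed_mask &= support  # closing must not push seeds outside the support
    labels = _label_components(seed_mask, min_seed_area_px)
    return SeedMap(labels.astype(np.int32), method="bespoke"), support


def bespoke_seeds(img: GrayImage, min_seed_area_px: Optional[int] = None) -> SeedMap:
    """Gradient/Otsu seeding for low-magnification images.

    ``img`` is expected to be illumination-corrected.  Pixels whose Sobel
    magnitude falls below the gradient Otsu threshold are treated as certain
    background; bright blobs (brightness above its own Otsu threshold) inside
    the remaining support become markers.  Components smaller than
    ``min_seed_area_px`` (default per magnification) are discarded.
    """
    if min_seed_area_px is None:
        min_seed_area_px = DEFAULT_MIN_SEED_AREA[img.magnification]
    if min_seed_area_px < 1:
        raise ParameterError("min_seed_area_px must be >= 1")
    seeds, _ = _bespoke(img, min_seed_area_px)
    return seeds


# ---------------------------------------------------------------------------
# Feineigle reconstruction (40x)


@dataclass
class ReconstructedImage:
    """Estimated optical density ``f`` (arbitrary additive offset).

    Produced by minimizing
    ``E(f) = sum_p (D_theta f(p) - g(p))^2 + lambda * sum_p |grad f(p)|^2``
    with pointwise Gauss-Seidel relaxation; the energy trace across sweeps is
    non-increasing (coordinate descent on a convex quadratic).
    """

    f: np.ndarray
    shear_theta: float
    lambda_reg: float
    sweeps_run: int
    final_energy: float
    converged: bool
    energy_trace: list[float] = field(default_factory=list)


@njit(cache=False)
def _gauss_seidel_sweep(indptr, indices, data, diag, b, x):  # pragma: no cover
    n = b.shape[0]
    for i in range(n):
        s = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            if j != i:
                s += data[k] * x[j]
        x[i] = (b[i] - s) / diag[i]


def _build_system(
    shape: tuple[int, int], theta_deg: float, lambda_reg: float
) -> sparse.csr_matrix:
    """Sparse design matrix A: data rows (D_theta f = g) then smoothness rows."""
    rows, cols = shape
    n = rows * cols
    idx = np.arange(n).reshape(shape)
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)

    r_list, c_list, v_list = [], [], []

    # data equations, one per pixel; boundary differences drop (Neumann)
    eq = idx
    if abs(c) > 0:
        r_list += [eq[:, :-1].ravel(), eq[:, :-1].ravel()]
        c_list += [idx[:, 1:].ravel(), idx[:, :-1].ravel()]
        v_list += [np.full((cols - 1) * rows, c), np.full((cols - 1) * rows, -c)]
    if abs(s) > 0:
        r_list += [eq[:-1, :].ravel(), eq[:-1, :].ravel()]
        c_list += [idx[1:, :].ravel(), idx[:-1, :].ravel()]
        v_list += [np.full((rows - 1) * cols, s), np.full((rows - 1) * cols, -s)]

    n_eq = n
    if lambda_reg > 0:
        w = np.sqrt(lambda_reg)
        # forward-difference gradient penalty, x then y
        m = rows * (cols - 1)
        eqx = n_eq + np.arange(m)
        r_list += [eqx, eqx]
        c_list += [idx[:, 1:].ravel(), idx[:, :-1].ravel()]
        v_list += [np.full(m, w), np.full(m, -w)]
        n_eq += m
        m = (rows - 1) * cols
        eqy = n_eq + np.arange(m)
        r_list += [eqy, eqy]
        c_list += [idx[1:, :].ravel(), idx[:-1, :].ravel()]
        v_list += [np.full(m, w), np.full(m, -w)]
        n_eq += m

    A = sparse.coo_matrix(
        (np.concatenate(v_list), (np.concatenate(r_list), np.concatenate(c_list))),
        shape=(n_eq, n),
    )
    return A.tocsr()


def feineigle_reconstruct(
    img: GrayImage,
    shear_theta: float = 45.0,
    lambda_reg: float = 0.01,
    max_sweeps: int = 4000,
    tol: float = 1e-4,
) -> ReconstructedImage:
    """Recover optical density by regularized directional integration.

    Minimizes ``E(f) = ||D_theta f - g||^2 + lambda * ||grad f||^2`` where
    ``g`` is the input centered to zero mean, using raster-order pointwise
    Gauss-Seidel updates (each pixel set to the closed-form minimizer with
    neighbors held fixed).  Stops when the relative energy decrease of a sweep
    drops below ``tol`` or after ``max_sweeps``; the best iterate is returned
    either way with ``converged`` reporting which happened.  The output is
    re-centered to zero mean (the additive offset is unobservable).
    """
    if lambda_reg < 0:
        raise ParameterError("lambda_reg must be >= 0")
    if max_sweeps < 1:
        raise ParameterError("max_sweeps must be >= 1")
    if not tol > 0:
        raise ParameterError("tol must be > 0")

    g = img.pixels - img.pixels.mean()
    shape = img.shape
    n = shape[0] * shape[1]

    A = _build_system(shape, shear_theta, lambda_reg)
    b_full = np.zeros(A.shape[0])
    b_full[:n] = g.ravel()

    M = (A.T @ A).tocsr()
    b = A.T @ b_full
    diag = M.diagonal().copy()
    diag[diag <= 0] = 1e-12  # unobserved pixels (possible when lambda = 0)
    M.sort_indices()

    x = np.zeros(n)
    energy = float(b_full @ b_full)
    trace = [energy]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        _gauss_seidel_sweep(M.indptr, M.indices, M.data, diag, b, x)
        r = A @ x - b_full
        e = float(r @ r)
        assert e <= trace[-1] + 1e-9 * max(1.0, trace[-1]), "energy increased"
        rel = (trace[-1] - e) / max(trace[-1], 1e-300)
        trace.append(e)
        if rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"Gauss-Seidel did not reach tol={tol} within {max_sweeps} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    f = x.reshape(shape)
    f = f - f.mean()
    return ReconstructedImage(
        f=f,
        shear_theta=shear_theta,
        lambda_reg=lambda_reg,
        sweeps_run=sweeps,
        final_energy=trace[-1],
        converged=converged,
        energy_trace=trace,
    )


def _feineigle_cell_masks(
    rec: ReconstructedImage, invert: bool = False, support_dilate_px: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """(support, core) masks from a two-threshold Otsu split of ``f``.

    ``core`` is the highest-density class (lowest if ``invert``).  The
    noise-driven ripple of the reconstructed background straddles the lower
    threshold, so the support is cut at the midpoint between the two
    thresholds (essentially ripple-free) and then dilated a few pixels to
    win back the attenuated rim of each cell.
    """
    f = rec.f
    span = float(f.max() - f.min())
    if span <= 0:
        z = np.zeros(f.shape, dtype=bool)
        return z, z
    fn = (f - f.min()) / span
    if invert:
        fn = 1.0 - fn
    try:
        t1, t2 = two_threshold_otsu(histogram256(fn))
    except DegenerateHistogramError:
        z = np.zeros(f.shape, dtype=bool)
        return z, z
    bins = np.clip((fn * 256).astype(np.int64), 0, 255)
    support = bins > t1 + 0.5 * (t2 - t1)
    if support_dilate_px > 0 and support.any():
        support = ndimage.binary_dilation(support, iterations=support_dilate_px)
    return support, bins > t2


def feineigle_seeds(
    rec: ReconstructedImage,
    h_frac: float = 0.5,
    invert: bool = False,
    min_seed_area_px: int = 1,
) -> SeedMap:
    """Markers from the distance transform of the reconstructed cell class.

    The reconstruction is split into three intensity classes by two-threshold
    Otsu; the highest class is taken as cell interior (``invert`` flips the
    polarity for specimens whose density runs the other way).  Seeds are the
    8-connected components of ``{d > h_frac * max(d)}`` where ``d`` is the
    Euclidean distance transform of that class — distance maxima mark cell
    centers and ``h_frac`` controls how aggressively touching cells split.
    """
    if not 0.0 < h_frac < 1.0:
        raise ParameterError("h_frac must be in (0, 1)")
    _, core = _feineigle_cell_masks(rec, invert=invert)
    if not core.any():
        warnings.warn(
            "empty cell class: no Feineigle seeds",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return SeedMap(np.zeros(rec.f.shape, dtype=np.int32), method="feineigle")
    d = distance_transform(core)
    seed_mask = d > h_frac * d.max()
    labels = _label_components(seed_mask, min_seed_area_px)
    return SeedMap(labels.astype(np.int32), method="feineigle")
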