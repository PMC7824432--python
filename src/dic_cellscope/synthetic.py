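"""Synthetic DIC-like micrographs with ground-truth instance masks.

The study conditions this generator emulates: in-vitro oral-mucosa cultures
viewed with differential interference contrast at 10x/20x/40x.  A DIC image
is approximately the directional derivative, along the shear axis, of the
specimen's optical density — cells appear as a pseudo-3D relief on a
mid-gray background with slowly varying illumination and sensor noise.

Cells come in two phenotypes: small convex ovals (keratinocyte-like;
equivalent diameters within 10-50 um) and elongated fiber-like cells
(fibroblast-like; axis ratio >= 3).  Optionally a *clump* of small adjacent
convex cells is placed to emulate dense colonies that real pipelines
under-segment into conglomerate regions.  Footprints are pairwise disjoint
(rejection-sampled placement) and the ground truth is returned as a
:class:`~dic_cellscope.segmentation.Labeling` plus a phenotype map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import DEFAULT_UM_PER_PX, GrayImage, ParameterError, directional_derivative
from .segmentation import Labeling


class PlacementError(RuntimeError):
    """Rejection sampling could not place all cells; lower the confluency."""


@dataclass(frozen=True)
class CellSpec:
    phenotype: str  # "convex" | "fiber"
    center: tuple[float, float]  # (row, col) px
    semi_axes: tuple[float, float]  # (a, b) px, a >= b
    orientation: float  # radians


@dataclass
class SyntheticScene:
    cells: list[CellSpec]
    shape: tuple[int, int]
    magnification: str
    um_per_px: float
    shear_theta: float
    bias_amplitude: float
    noise_sigma: float
    rng_seed: int
    day: Optional[int]
    truth: Labeling
    phenotypes: dict[int, str] = field(default_factory=dict)
    image_id: str = ""


def _ellipse_mask(
    shape: tuple[int, int], center, semi_axes, orientation
) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    """Bounding slices, boolean footprint, and normalized radius inside it."""
    a, b = semi_axes
    r0, c0 = center
    ext = math.ceil(max(a, b)) + 2
    sl_r = slice(max(0, int(r0) - ext), min(shape[0], int(r0) + ext + 1))
    sl_c = slice(max(0, int(c0) - ext), min(shape[1], int(c0) + ext + 1))
    rr, cc = np.mgrid[sl_r, sl_c]
    dr = rr - r0
    dc = cc - c0
    ca, sa = math.cos(orientation), math.sin(orientation)
    u = dc * ca + dr * sa
    v = -dc * sa + dr * ca
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return sl_r, sl_c, r <= 1.0, r


def make_scene(
    n_convex: int,
    n_fiber: int,
    *,
    shape: tuple[int, int] = (512, 512),
    magnification: str = "10x",
    um_per_px: Optional[float] = None,
    convex_diameter_um: tuple[float, float] = (30.0, 44.0),
    convex_axis_ratio: tuple[float, float] = (1.0, 1.3),
    fiber_length_um: tuple[float, float] = (90.0, 140.0),
    fiber_width_um: tuple[float, float] = (10.0, 15.0),
    clump_cells: int = 0,
    clump_diameter_um: tuple[float, float] = (14.0, 20.0),
    shear_theta: float = 45.0,
    bias_amplitude: float = 0.1,
    noise_sigma: float = 0.02,
    margin_px: int = 2,
    max_attempts: int = 10000,
    day: Optional[int] = None,
    rng_seed: int = 0,
) -> SyntheticScene:
    """Place cells by rejection sampling; deterministic for a given seed.

    ``n_convex`` convex ovals and ``n_fiber`` elongated cells are placed with
    pairwise-disjoint footprints at least ``margin_px`` apart.  If
    ``clump_cells`` > 0, that many extra *small* convex cells are placed as a
    tight clump (adjacent footprints, no margin between clump members) —
    ground truth keeps them as separate cells, but a realistic pipeline tends
    to merge them into one conglomerate region.
    """
    if n_convex < 0 or n_fiber < 0 or clump_cells < 0:
        raise ParameterError("cell counts must be >= 0")
    if um_per_px is None:
        um_per_px = DEFAULT_UM_PER_PX[magnification]
    rng = np.random.default_rng([rng_seed, 0])
    occupied = np.zeros(shape, dtype=bool)  # footprints dilated by margin
    labels = np.zeros(shape, dtype=np.int32)
    cells: list[CellSpec] = []
    phenotypes: dict[int, str] = {}
    border = 4

    def try_place(phenotype, a, b, center=None, internal_margin=margin_px) -> bool:
        orientation = rng.uniform(0.0, math.pi)
        if center is None:
            ext = max(a, b) + border
            if shape[0] - 2 * ext <= 0 or shape[1] - 2 * ext <= 0:
                return False
            center = (
                rng.uniform(ext, shape[0] - ext),
                rng.uniform(ext, shape[1] - ext),
            )
        sl_r, sl_c, mask, _ = _ellipse_mask(shape, center, (a, b), orientation)
        if mask.sum() < 4:
            return False
        # footprint must stay inside the raster
        full = int(np.pi * a * b * 0.95)
        if mask.sum() < full:
            return False
        grown = _dilate(mask, internal_margin)
        if occupied[sl_r, sl_c][grown].any():
            return False
        rid = len(cells) + 1
        labels[sl_r, sl_c][mask] = rid
        occupied[sl_r, sl_c] |= _dilate(mask, margin_px)
        cells.append(CellSpec(phenotype, tuple(center), (a, b), orientation))
        phenotypes[rid] = phenotype
        return True

    def sample_until(phenotype, sampler, count):
        placed = 0
        attempts = 0
        while placed < count:
            if attempts >= max_attempts:
                raise PlacementError(
                    f"could not place {count} {phenotype} cells within "
                    f"{max_attempts} attempts; lower the confluency"
                )
            a, b = sampler()
            if try_place(phenotype, a, b):
                placed += 1
            attempts += 1

    def convex_axes():
        d = rng.uniform(*convex_diameter_um) / um_per_px
        q = rng.uniform(*convex_axis_ratio)
        b = d / (2.0 * math.sqrt(q))
        return b * q, b  # preserves equivalent diameter d

    def fiber_axes():
        length = rng.uniform(*fiber_length_um) / um_per_px
        width = rng.uniform(*fiber_width_um) / um_per_px
        return length / 2.0, width / 2.0

    sample_until("convex", convex_axes, n_convex)
    sample_until("fiber", fiber_axes, n_fiber)

    if clump_cells:
        _place_clump(
            rng, shape, labels, occupied, cells, phenotypes,
            clump_cells, clump_diameter_um, um_per_px, margin_px,
            max_attempts, border,
        )

    truth = Labeling(
        labels, magnification=magnification, image_id=f"syn-{rng_seed:06d}"
    )
    return SyntheticScene(
        cells=cells,
        shape=shape,
        magnification=magnification,
        um_per_px=float(um_per_px),
        shear_theta=shear_theta,
        bias_amplitude=bias_amplitude,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
        day=day,
        truth=truth,
        phenotypes=phenotypes,
        image_id=truth.image_id,
    )


def _dilate(mask: np.ndarray, r: int) -> np.ndarray:
    if r <= 0:
        return mask
    from scipy import ndimage

    return ndimage.binary_dilation(mask, iterations=r)


def _place_clump(
    rng, shape, labels, occupied, cells, phenotypes,
    clump_cells, clump_diameter_um, um_per_px, margin_px, max_attempts, border,
) -> None:
    """Place small convex cells with adjacent (0-gap) footprints."""
    for attempt in range(max_attempts):
        d0 = rng.uniform(*clump_diameter_um) / um_per_px
        ext = clump_cells * d0
        center0 = (
            rng.uniform(ext + border, shape[0] - ext - border),
            rng.uniform(ext + border, shape[1] - ext - border),
        )
        snapshot = (labels.copy(), occupied.copy(), list(cells), dict(phenotypes))
        placed = []
        ok = True
        for i in range(clump_cells):
            d = rng.uniform(*clump_diameter_um) / um_per_px
            a = b = d / 2.0
            for _ in range(200):
                if not placed:
                    center = center0
                else:
                    prev = placed[rng.integers(len(placed))]
                    ang = rng.uniform(0, 2 * math.pi)
                    dist = prev.semi_axes[0] + a + 0.5
                    center = (
                        prev.center[0] + dist * math.sin(ang),
                        prev.center[1] + dist * math.cos(ang),
                    )
                orientation = 0.0
                sl_r, sl_c, mask, _ = _ellipse_mask(shape, center, (a, b), orientation)
                full = int(np.pi * a * b * 0.95)
                if mask.sum() < max(full, 4):
                    continue
                # clump members may touch each other but not outside cells
                window = labels[sl_r, sl_c]
                grown = _dilate(mask, 1)
                clump_ids = {len(snapshot[2]) + 1 + j for j in range(len(placed))}
                overlapping = set(np.unique(window[grown])) - {0} - clump_ids
                if overlapping:
                    continue
                if window[mask].any():
                    continue
                rid = len(cells) + 1
                labels[sl_r, sl_c][mask] = rid
                occupied[sl_r, sl_c] |= _dilate(mask, margin_px)
                spec = CellSpec("convex", tuple(center), (a, b), orientation)
                cells.append(spec)
                phenotypes[rid] = "convex"
                placed.append(spec)
                break
            else:
                ok = False
                break
        if ok:
            return
        labels[:], occupied[:] = snapshot[0], snapshot[1]
        del cells[len(snapshot[2]):]
        for k in list(phenotypes):
            if k not in snapshot[3]:
                del phenotypes[k]
    raise PlacementError("could not place the clump; lower the confluency")


def height_map(scene: SyntheticScene) -> np.ndarray:
    """Sum of cosine-tapered per-cell bumps (the 'optical density' surface).

    The cosine taper keeps every cell's support compact and exactly equal to
    its ground-truth footprint, so IoU scoring against the truth is
    unambiguous.
    """
    h = np.zeros(scene.shape)
    for cell in scene.cells:
        sl_r, sl_c, mask, r = _ellipse_mask(
            scene.shape, cell.center, cell.semi_axes, cell.orientation
        )
        # optical path length scales with cell thickness, itself proportional
        # to the cell's width: without this, thin fibers would dominate the
        # relief contrast with unrealistically steep slopes
        amp = cell.semi_axes[1]
        bump = amp * 0.5 * (1.0 + np.cos(np.pi * np.clip(r, 0.0, 1.0)))
        h[sl_r, sl_c][mask] += bump[mask]
    peak = h.max()
    if peak > 0:
        h /= peak
    return h


def render_dic(scene: SyntheticScene) -> GrayImage:
    """Render the pseudo-3D DIC relief of a scene.

    ``image = 0.5 + D_theta(height) scaled to +/- 0.3 + polynomial
    illumination bias + Gaussian noise``, clipped to [0, 1].  Bias and noise
    come from the scene's own rng stream, so rendering is deterministic.
    """
    h = height_map(scene)
    d = directional_derivative(h, scene.shear_theta)
    peak = float(np.abs(d).max())
    img = np.full(scene.shape, 0.5)
    if peak > 0:
        img += 0.3 * d / peak

    rng = np.random.default_rng([scene.rng_seed, 7])
    # coefficients are drawn even at zero amplitude so the noise stream below
    # is identical for bias-on and bias-off renders of the same scene
    coef = rng.uniform(-1.0, 1.0, size=5)
    if scene.bias_amplitude > 0:
        ry = np.linspace(-1.0, 1.0, scene.shape[0])[:, None]
        rx = np.linspace(-1.0, 1.0, scene.shape[1])[None, :]
        bias = (
            coef[0] * rx + coef[1] * ry + coef[2] * rx * ry
            + coef[3] * rx**2 + coef[4] * ry**2
        )
        bias -= bias.mean()
        b_peak = float(np.abs(bias).max())
        if b_peak > 0:
            img += scene.bias_amplitude * bias / b_peak
    if scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, size=scene.shape)

    return GrayImage(
        pixels=np.clip(img, 0.0, 1.0),
        magnification=scene.magnification,
        um_per_px=scene.um_per_px,
        day=scene.day,
        image_id=scene.image_id,
    )
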