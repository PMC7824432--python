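"""Reading and writing images, label rasters, and the per-directory manifest.

The manifest is a CSV with columns ``filename, magnification, day, um_per_px``
describing every micrograph in a directory.  Integer images (8/16-bit) are
mapped to ``[0, 1]`` by division by the dtype maximum; float images must
already be in ``[0, 1]``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import DEFAULT_UM_PER_PX, GrayImage, ParameterError

logger = logging.getLogger("dic_cellscope")

MANIFEST_COLUMNS = ("filename", "magnification", "day", "um_per_px")


def load_image(
    path: str | Path,
    magnification: str,
    day: Optional[int] = None,
    um_per_px: Optional[float] = None,
    image_id: Optional[str] = None,
) -> GrayImage:
    """Load a single-channel PNG/TIFF as a calibrated :class:`GrayImage`."""
    path = Path(path)
    raw = iio.imread(path)
    if raw.ndim == 3:
        if raw.shape[2] == 1:
            raw = raw[:, :, 0]
        else:
            raise ParameterError(
                f"{path.name}: expected a single-channel image, got {raw.shape}"
            )
    if np.issubdtype(raw.dtype, np.integer):
        px = raw.astype(np.float64) / np.iinfo(raw.dtype).max
    else:
        px = raw.astype(np.float64)
        if px.min() < 0 or px.max() > 1:
            raise ParameterError(f"{path.name}: float image must lie in [0, 1]")
    if um_per_px is None:
        um_per_px = DEFAULT_UM_PER_PX[magnification]
        logger.warning(
            "%s: no um_per_px supplied; using placeholder %.3g um/px for %s",
            path.name, um_per_px, magnification,
        )
    return GrayImage(
        pixels=px,
        magnification=magnification,
        um_per_px=float(um_per_px),
        day=None if day is None or (isinstance(day, float) and np.isnan(day)) else int(day),
        image_id=image_id or path.stem,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a manifest CSV."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_manifest_images(manifest_path: str | Path) -> list[GrayImage]:
    """Load every image referenced by a manifest, resolving relative paths."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    images = []
    for row in df.itertuples(index=False):
        img_path = manifest_path.parent / str(row.filename)
        images.append(
            load_image(
                img_path,
                magnification=str(row.magnification),
                day=None if pd.isna(row.day) else int(row.day),
                um_per_px=None if pd.isna(row.um_per_px) else float(row.um_per_px),
            )
        )
    return images


def save_gray_image(path: str | Path, img: GrayImage) -> None:
    """Write intensities as 16-bit grayscale PNG/TIFF."""
    data = np.clip(img.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), np.round(data * 65535).astype(np.uint16))


def save_label_image(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label raster as 16-bit PNG/TIFF."""
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ParameterError("more than 65535 labels cannot be stored as 16-bit")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def save_overlay(path: str | Path, labels: np.ndarray, seed: int = 0) -> None:
    """Write a color overlay (random palette, black background) of a labeling."""
    labels = np.asarray(labels)
    n = int(labels.max())
    rng = np.random.default_rng(seed)
    palette = np.zeros((n + 1, 3), dtype=np.uint8)
    if n:
        palette[1:] = rng.integers(60, 256, size=(n, 3), dtype=np.uint8)
    iio.imwrite(Path(path), palette[labels])
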