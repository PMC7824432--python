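"""Shared fixtures: synthetic scenes and segmentation results reused across tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from dic_cellscope import segment_image
from dic_cellscope.core import DegenerateImageWarning, correct_illumination, normalize_brightness
from dic_cellscope.synthetic import make_scene, render_dic


def best_iou(labels: np.ndarray, truth_mask: np.ndarray) -> float:
    """IoU of the best-matching region for one ground-truth mask."""
    best = 0.0
    for rid in set(np.unique(labels[truth_mask])) - {0}:
        rm = labels == rid
        best = max(best, (rm & truth_mask).sum() / (rm | truth_mask).sum())
    return best


def recall_at_iou(labels: np.ndarray, truth: np.ndarray, threshold: float = 0.5):
    """(hits, total) of ground-truth cells matched by a region above IoU threshold."""
    n = int(truth.max())
    hits = sum(1 for r in range(1, n + 1) if best_iou(labels, truth == r) > threshold)
    return hits, n


@pytest.fixture(scope="session")
def scene_12_4():
    """Non-touching 10x culture: 12 convex + 4 fiber cells, fixed seed."""
    scene = make_scene(12, 4, rng_seed=0)
    return scene, render_dic(scene)


@pytest.fixture(scope="session")
def corrected_12_4(scene_12_4):
    _, img = scene_12_4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateImageWarning)
        return correct_illumination(normalize_brightness(img))


@pytest.fixture(scope="session")
def segmented_12_4(scene_12_4):
    scene, img = scene_12_4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment_image(img)


@pytest.fixture(scope="session")
def scene_40x_3():
    """Three convex cells at 40x for the Feineigle path, fixed seed."""
    scene = make_scene(
        3, 0, shape=(224, 224), magnification="40x",
        convex_diameter_um=(18, 22), rng_seed=3,
    )
    return scene, render_dic(scene)
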