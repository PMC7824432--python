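"""Population-level analysis: clustering, semantics, shares, timelines.

Features pooled across all images are clustered with k-means (k = 3).  The
two large clusters correspond to the two morphological phenotypes seen in
mixed mucosal cultures — small convex keratinocyte-like cells ("blue") and
elongated fiber-like fibroblast-like cells ("red") — while the smallest
cluster ("green") collects conglomerates and segmentation artifacts.  An
isomap embedding provides a visual compactness check of the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

from .core import ParameterError
from .morphometry import FEATURE_COLUMNS

SEMANTIC_LABELS = ("blue", "red", "green")

_MAX_LLOYD_ITER = 300


@dataclass
class ClusterParams:
    """k-means configuration; defaults give a deterministic k = 3 fit."""

    k: int = 3
    n_restarts: int = 10
    rng_seed: int = 17
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.n_restarts < 1:
            raise ParameterError("n_restarts must be >= 1")


@dataclass
class ClusterResult:
    """Fitted k-means model plus optional semantic labels.

    ``centroids`` live in the (standardized) 6-feature space; ``assignment``
    holds one cluster id per table row; ``semantic`` maps cluster id to
    {"blue", "red", "green"} once :func:`assign_semantics` has run.
    """

    centroids: np.ndarray
    assignment: np.ndarray
    inertia: float
    semantic: Optional[dict[int, str]] = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def semantic_labels(self) -> np.ndarray:
        if self.semantic is None:
            raise ParameterError("semantics not assigned yet")
        lut = np.array([self.semantic[i] for i in range(self.k)])
        return lut[self.assignment]


def _feature_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    X = np.asarray(table, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError("feature array must be 2-D")
    return X


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[i] = X[rng.integers(n)]
        else:
            centroids[i] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centroids[i]) ** 2).sum(axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = _kmeans_pp_init(X, k, rng)
    prev_inertia = np.inf
    assign = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(_MAX_LLOYD_ITER):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), new_assign].sum())
        # coordinate descent: assignment then mean updates never increase cost
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia), (
            "k-means inertia increased"
        )
        # repair empty clusters by reseeding from the farthest point
        counts = np.bincount(new_assign, minlength=k)
        for empty in np.flatnonzero(counts == 0):
            far = int(d2[np.arange(len(X)), new_assign].argmax())
            centroids[empty] = X[far]
            d2[:, empty] = ((X - centroids[empty]) ** 2).sum(axis=1)
            new_assign = d2.argmin(axis=1)
            inertia = float(d2[np.arange(len(X)), new_assign].sum())
            counts = np.bincount(new_assign, minlength=k)
        if np.array_equal(new_assign, assign) and np.isfinite(prev_inertia):
            break
        assign = new_assign
        prev_inertia = inertia
        for c in range(k):
            pts = X[assign == c]
            if len(pts):
                centroids[c] = pts.mean(axis=0)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), assign].sum())
    return centroids, assign, inertia


def fit_kmeans(
    table: pd.DataFrame | np.ndarray, params: Optional[ClusterParams] = None
) -> ClusterResult:
    """Deterministic k-means (Lloyd + k-means++, best of ``n_restarts``).

    Features are z-scored per column by default — the six features mix logs,
    lengths and ratios, and unscaled Euclidean distance would be dominated by
    the perimeter.  Identical input and seed give a bit-exact result.
    """
    params = params or ClusterParams()
    X = _feature_matrix(table)
    if np.unique(X, axis=0).shape[0] < params.k:
        raise ParameterError(
            f"need at least k={params.k} distinct feature rows"
        )
    if params.standardize:
        X = _standardize(X)
    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    for r in range(params.n_restarts):
        rng = np.random.default_rng([params.rng_seed, r])
        cand = _lloyd(X, params.k, rng)
        if best is None or cand[2] < best[2]:
            best = cand
    centroids, assign, inertia = best  # type: ignore[misc]
    return ClusterResult(centroids=centroids, assignment=assign, inertia=inertia)


def assign_semantics(res: ClusterResult, table: pd.DataFrame) -> ClusterResult:
    """Attach blue/red/green semantics to a k = 3 clustering.

    green = the smallest cluster (mostly regions where segmentation failed:
    conglomerates, artifacts); of the remaining two, red = higher mean
    eccentricity (elongated, fiber-like cells) and blue = the other (small
    convex cells).  Ties break on mean major axis (longer -> red).
    """
    if res.k != 3:
        raise ParameterError("semantic labels are defined for k = 3 only")
    counts = res.counts()
    order = np.argsort(counts, kind="stable")
    green = int(order[0])
    rest = sorted(int(c) for c in order[1:])
    ecc = table["eccentricity"].to_numpy(dtype=np.float64)
    major = table["major_axis"].to_numpy(dtype=np.float64)

    def mean_of(cid: int, values: np.ndarray) -> float:
        sel = res.assignment == cid
        return float(values[sel].mean()) if sel.any() else -np.inf

    e0, e1 = mean_of(rest[0], ecc), mean_of(rest[1], ecc)
    if e0 == e1:
        e0, e1 = mean_of(rest[0], major), mean_of(rest[1], major)
    red, blue = (rest[0], rest[1]) if e0 > e1 else (rest[1], rest[0])
    return replace(res, semantic={blue: "blue", red: "red", green: "green"})


def _round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def cluster_shares(
    counts: Mapping[str, int] | ClusterResult,
) -> pd.DataFrame:
    """Cluster sizes and percentage shares (half-up, 2 decimals).

    Accepts either per-semantic-class counts or a ClusterResult with
    semantics attached.  Shares sum to 100.00 up to rounding.
    """
    if isinstance(counts, ClusterResult):
        labels = counts.semantic_labels()
        counts = {
            lab: int((labels == lab).sum()) for lab in SEMANTIC_LABELS
        }
    total = sum(counts.values())
    if total < 1:
        raise ParameterError("total count must be >= 1")
    rows = [
        (label, int(c), _round_half_up(100.0 * c / total))
        for label, c in counts.items()
    ]
    return pd.DataFrame(rows, columns=["semantic_label", "count", "share_pct"])


def isomap_embed(
    table: pd.DataFrame | np.ndarray,
    n_neighbors: int = 10,
    standardize: bool = True,
) -> np.ndarray:
    """2-D isomap embedding of the feature rows.

    Classical isomap (k-NN graph, geodesic shortest paths, 2-component
    classical MDS), deterministic up to sign/rotation.  Raises when the
    neighborhood graph is disconnected, with advice to raise ``n_neighbors``.
    """
    X = _feature_matrix(table)
    if X.shape[0] < n_neighbors + 1:
        raise ParameterError("need at least n_neighbors + 1 rows")
    if standardize:
        X = _standardize(X)
    graph = kneighbors_graph(X, n_neighbors=n_neighbors, mode="connectivity")
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ParameterError(
            f"neighborhood graph has {n_comp} components; "
            "increase n_neighbors for a connected embedding"
        )
    return Isomap(n_neighbors=n_neighbors, n_components=2).fit_transform(X)


def timeline_summary(
    res: ClusterResult,
    table: pd.DataFrame,
    images_per_day: Optional[Mapping[int, int]] = None,
) -> pd.DataFrame:
    """Average number of regions per image, per culture day and class.

    ``images_per_day`` should come from the acquisition manifest so that
    images without any region still count in the denominator; without it the
    distinct image ids present in the table are used.
    """
    if table["day"].isna().any():
        bad = table.index[table["day"].isna()].tolist()
        raise ParameterError(f"rows without day metadata: {bad}")
    labels = res.semantic_labels()
    days = table["day"].astype(int).to_numpy()
    if images_per_day is None:
        images_per_day = (
            table.assign(day=days).groupby("day")["image_id"].nunique().to_dict()
        )
    rows = []
    for day in sorted(set(days)):
        n_images = int(images_per_day.get(day, 0))
        if n_images < 1:
            raise ParameterError(f"day {day} has regions but no images")
        sel = days == day
        for label in SEMANTIC_LABELS:
            count = int((labels[sel] == label).sum())
            rows.append((day, label, count / n_images, n_images))
    return pd.DataFrame(
        rows, columns=["day", "semantic_label", "avg_regions_per_image", "n_images"]
    )
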