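"""End-to-end orchestration: segment -> features -> cluster -> reports.

``run_pipeline`` consumes a manifest CSV, segments every image by its
magnification, pools the per-region features, clusters them with k-means
(k = 3), attaches blue/red/green semantics, and writes
``features.csv``, ``clusters.csv``, ``shares.csv``, ``timeline.csv``,
``embedding.csv`` plus per-image label rasters.  Identical inputs, config
and seed give byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import DegenerateImageWarning, GrayImage, ParameterError
from .io import load_image, read_manifest, save_label_image, save_overlay
from .morphometry import TABLE_COLUMNS, build_feature_table
from .population import (
    ClusterParams,
    assign_semantics,
    cluster_shares,
    fit_kmeans,
    isomap_embed,
    timeline_summary,
)
from .segmentation import (
    DEFAULT_MIN_AREA_PX,
    Labeling,
    SegmentationConfig,
    segment_image,
)
from .seeding import DEFAULT_MIN_SEED_AREA

logger = logging.getLogger("dic_cellscope")

_FLOAT_FMT = "%.9g"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one flat, serializable record."""

    sigma_frac: float = 0.125
    shear_theta: float = 45.0
    lambda_reg: float = 0.01
    max_sweeps: int = 4000
    tol: float = 1e-4
    h_frac: float = 0.5
    invert_feineigle: bool = False
    split_factor: float = 2.0
    background_margin_px: int = 5
    min_split_component_px: int = 64
    min_area_10x: int = DEFAULT_MIN_AREA_PX["10x"]
    min_area_20x: int = DEFAULT_MIN_AREA_PX["20x"]
    min_area_40x: int = DEFAULT_MIN_AREA_PX["40x"]
    min_seed_area_10x: int = DEFAULT_MIN_SEED_AREA["10x"]
    min_seed_area_20x: int = DEFAULT_MIN_SEED_AREA["20x"]
    min_seed_area_40x: int = DEFAULT_MIN_SEED_AREA["40x"]
    k: int = 3
    n_restarts: int = 10
    rng_seed: int = 17
    standardize: bool = True
    isomap_neighbors: int = 10
    write_overlays: bool = False

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            min_area_px={
                "10x": self.min_area_10x,
                "20x": self.min_area_20x,
                "40x": self.min_area_40x,
            },
            split_factor=self.split_factor,
            background_margin_px=self.background_margin_px,
            min_split_component_px=self.min_split_component_px,
        )

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            k=self.k,
            n_restarts=self.n_restarts,
            rng_seed=self.rng_seed,
            standardize=self.standardize,
        )

    def min_seed_area(self, magnification: str) -> int:
        return getattr(self, f"min_seed_area_{magnification}")

    def to_file(self, path: str | Path) -> None:
        """Write as flat ``key=value`` lines."""
        lines = [
            f"{f.name}={getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key=value`` config; unknown keys are rejected."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParameterError(f"line {lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in known:
                raise ParameterError(f"line {lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    labelings: list[Labeling]
    features: pd.DataFrame
    clusters: Optional[pd.DataFrame]
    shares: Optional[pd.DataFrame]
    timeline: Optional[pd.DataFrame]
    n_failed: int
    exit_code: int = 0


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def segment_with_config(img: GrayImage, cfg: PipelineConfig) -> Labeling:
    """Run the segmentation stage with pipeline-level settings."""
    return segment_image(
        img,
        cfg.segmentation_config(),
        sigma_frac=cfg.sigma_frac,
        min_seed_area_px=cfg.min_seed_area(img.magnification),
        shear_theta=cfg.shear_theta,
        lambda_reg=cfg.lambda_reg,
        max_sweeps=cfg.max_sweeps,
        tol=cfg.tol,
        h_frac=cfg.h_frac,
        invert_feineigle=cfg.invert_feineigle,
    )


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    cfg: Optional[PipelineConfig] = None,
    images: Optional[list[GrayImage]] = None,
) -> PipelineResult:
    """Run the whole analysis for one manifest.

    Per-image failures are logged and skipped (the exit code is then
    nonzero); a run with zero usable regions writes empty outputs with the
    full column schema and a warning instead of failing.  ``images`` may be
    supplied directly (e.g. synthetic scenes) to bypass file loading, in
    which case the manifest is only used for day bookkeeping.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    n_failed = 0
    labelings: list[Labeling] = []
    used_images: list[GrayImage] = []
    images_per_day: dict[int, int] = {}
    try:
        if images is None:
            images = []
            for row in manifest.itertuples(index=False):
                try:
                    images.append(
                        load_image(
                            manifest_path.parent / str(row.filename),
                            magnification=str(row.magnification),
                            day=None if pd.isna(row.day) else int(row.day),
                            um_per_px=None if pd.isna(row.um_per_px) else float(row.um_per_px),
                        )
                    )
                except Exception:
                    logger.exception("failed to load %s", row.filename)
                    n_failed += 1
        (out / "labels").mkdir(exist_ok=True)
        for img in images:
            if img.day is not None:
                images_per_day[img.day] = images_per_day.get(img.day, 0) + 1
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DegenerateImageWarning)
                    lab = segment_with_config(img, cfg)
                labelings.append(lab)
                used_images.append(img)
                save_label_image(out / "labels" / f"{img.image_id}.tif", lab.labels)
                if cfg.write_overlays:
                    save_overlay(out / "labels" / f"{img.image_id}_overlay.png", lab.labels)
                logger.info("%s: %d regions", img.image_id, lab.n_regions)
            except Exception:
                logger.exception("segmentation failed for %s", img.image_id)
                n_failed += 1

        features = build_feature_table(labelings, used_images)
        _write_csv(features, out / "features.csv")

        clusters = shares = timeline = None
        params = cfg.cluster_params()
        if len(features) >= params.k:
            res = fit_kmeans(features, params)
            res = assign_semantics(res, features)
            clusters = features.copy()
            clusters["cluster_id"] = res.assignment
            clusters["semantic_label"] = res.semantic_labels()
            _write_csv(clusters, out / "clusters.csv")
            shares = cluster_shares(res)
            _write_csv(shares, out / "shares.csv")
            if features["day"].notna().all() and len(features):
                timeline = timeline_summary(res, features, images_per_day or None)
                _write_csv(timeline, out / "timeline.csv")
            if len(features) >= cfg.isomap_neighbors + 1:
                try:
                    emb = isomap_embed(features, n_neighbors=cfg.isomap_neighbors)
                    emb_df = features[["image_id", "region_id"]].copy()
                    emb_df["isomap_1"] = emb[:, 0]
                    emb_df["isomap_2"] = emb[:, 1]
                    _write_csv(emb_df, out / "embedding.csv")
                except ParameterError as exc:
                    logger.warning("isomap skipped: %s", exc)
        else:
            warnings.warn(
                "too few regions to cluster: wrote features only",
                DegenerateImageWarning,
                stacklevel=2,
            )
            for name in ("clusters", "shares", "timeline"):
                _write_csv(pd.DataFrame(columns=list(TABLE_COLUMNS)), out / f"{name}.csv")
        exit_code = 1 if n_failed else 0
        return PipelineResult(
            labelings=labelings,
            features=features,
            clusters=clusters,
            shares=shares,
            timeline=timeline,
            n_failed=n_failed,
            exit_code=exit_code,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
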