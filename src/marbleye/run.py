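"""Batch orchestration: manifest-driven feature extraction and model fitting.

This is the batch-processor layer that ties the stages together: read a
manifest of photographs, push each through segmentation → fleck labelling →
feature computation, and append one row per image to a features CSV whose
header comments embed the run provenance (config hash, seed, package
version).  ``run_fit`` then performs the grouped split, Venetian-blinds CV,
boosted-tree fit and evaluation, writing a JSON report and a predictions
CSV.  Per-image failures are logged and skipped — a corrupt photograph
never aborts a batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import InvalidInputError, MarbleyeError
from .features import (
    MarblingFeatureVector,
    compute_features,
    label_flecks,
    partition_flecks,
)
from .model import fit_model, grouped_split, variable_importance, venetian_blinds
from .segmentation import (
    BeefMask,
    FleckMask,
    RibEyeImage,
    binarize_flecks,
    resize_standard,
    segment_beef,
)

__all__ = [
    "ImageResult",
    "process_image",
    "load_image",
    "load_manifest",
    "run_extract",
    "write_features_csv",
    "read_features_csv",
    "run_fit",
]

logger = logging.getLogger("marbleye")

MANIFEST_COLUMNS = ("image_path", "sample_id", "breed", "side", "duplicate_index")


@dataclass
class ImageResult:
    """Output of the per-image pipeline."""

    features: MarblingFeatureVector
    beef: BeefMask
    flecks: FleckMask
    n_discarded: int


def process_image(image: RibEyeImage, config: RunConfig | None = None) -> ImageResult:
    """Standardize, segment, binarize, label and measure one image."""
    config = config or RunConfig()
    image = resize_standard(image, config.resize_target)
    beef = segment_beef(image, config.threshold_spec)
    flecks = binarize_flecks(image, beef, method=config.binarization)
    assert not (flecks.mask & ~beef.mask).any(), "fleck mask escaped the beef region"
    fleck_list = label_flecks(flecks, image.px_per_mm, connectivity=config.connectivity)
    partition = partition_flecks(fleck_list, config.small_min, config.small_max)
    features = compute_features(partition, beef)
    if partition.discarded:
        logger.debug(
            "%s: discarded %d sub-%gmm2 flecks", image.sample_id,
            len(partition.discarded), config.small_min,
        )
    return ImageResult(
        features=features, beef=beef, flecks=flecks, n_discarded=len(partition.discarded)
    )


def load_image(path: str | Path, config: RunConfig, **provenance) -> RibEyeImage:
    """Read an 8-bit RGB PNG/TIFF into a calibrated :class:`RibEyeImage`."""
    from PIL import Image

    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return RibEyeImage(pixels=pixels, px_per_mm=config.px_per_mm, **provenance)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a manifest CSV."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidInputError(f"cannot read manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"manifest is missing columns: {missing}")
    dupes = df.duplicated(subset=["sample_id", "side", "duplicate_index"])
    if dupes.any():
        raise InvalidInputError(
            "manifest has duplicate (sample_id, side, duplicate_index) rows"
        )
    return df


def run_extract(
    config: RunConfig, manifest: pd.DataFrame, base_dir: str | Path = "."
) -> tuple[pd.DataFrame, int]:
    """Extract one feature row per manifest image.

    Returns ``(features table, failure count)``.  Unreadable or
    unsegmentable images are logged and skipped, never fatal.
    """
    base = Path(base_dir)
    rows = []
    n_failed = 0
    for _, m in manifest.iterrows():
        try:
            img = load_image(
                base / m["image_path"],
                config,
                sample_id=str(m["sample_id"]),
                side=str(m["side"]),
                duplicate_index=int(m["duplicate_index"]),
            )
            res = process_image(img, config)
        except (MarbleyeError, OSError) as exc:
            n_failed += 1
            logger.warning("skipping %s: %s", m["image_path"], exc)
            continue
        row = {
            "sample_id": m["sample_id"],
            "side": m["side"],
            "duplicate_index": m["duplicate_index"],
            "breed": m.get("breed", ""),
        }
        row.update(res.features.as_dict())
        if "score" in m and pd.notna(m["score"]):
            row["score"] = float(m["score"])
        rows.append(row)
        logger.info("processed %s (%s flecks retained)", m["image_path"], res.features.TMN)
    if n_failed:
        logger.warning("%d image(s) failed and were skipped", n_failed)
    return pd.DataFrame(rows), n_failed


def write_features_csv(
    df: pd.DataFrame, path: str | Path, config: RunConfig, extra: dict | None = None
) -> None:
    """Write a features CSV with '#'-prefixed provenance header comments."""
    meta = {"marbleye_version": __version__, "config_hash": config.hash(), "seed": config.seed}
    meta.update(extra or {})
    with open(path, "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_fit(
    config: RunConfig,
    features: pd.DataFrame | str | Path,
    report_path: str | Path | None = None,
    predictions_path: str | Path | None = None,
) -> dict:
    """Grouped split → Venetian-blinds CV → boosted-tree fit → evaluation.

    Returns the report dict; optionally writes the JSON report and the
    predictions CSV (sample_id, observed, predicted, split role).
    """
    if not isinstance(features, pd.DataFrame):
        features = read_features_csv(features)
    if "score" not in features.columns:
        raise InvalidInputError(
            "features table has no 'score' column; expected schema: "
            "sample_id, side, duplicate_index, breed, SMN, SMA, TMN, TMA, MR, F, "
            "beef_area_mm2, score"
        )
    split = grouped_split(features, config.test_fraction, seed=config.seed)
    n_train_rows = int(features["sample_id"].astype(str).isin(split.train_ids).sum())
    cv = venetian_blinds(n_train_rows, config.n_folds, window=config.cv_window)
    fit = fit_model(features, split, cv=cv, grid=config.grid, seed=config.seed)
    report = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "marbleye_version": __version__,
        "split": {"train_ids": list(split.train_ids), "test_ids": list(split.test_ids)},
        "n_folds": cv.n_folds,
        "best_params": fit.best_params,
        "metrics": {
            "r2_pred": fit.r2_pred,
            "rmsep": fit.rmsep,
            "r2_cv": fit.r2_cv,
            "rmse_cv": fit.rmse_cv,
        },
        "cv_rmse_per_fold": fit.cv_rmse_per_fold,
        "importance": [[name, w] for name, w in variable_importance(fit)],
        "messages": fit.messages,
    }
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, indent=1, sort_keys=True))
    if predictions_path is not None and fit.predictions is not None:
        fit.predictions.to_csv(predictions_path, index=False)
    report["_fit"] = fit  # in-memory only; not serialized
    return report
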