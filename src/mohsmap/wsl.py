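"""Two-stage weakly supervised training from image-level diagnoses.

Expert segmentation is labor-intensive; the weakly supervised alternative
trains without masks.  Stage 1 labels every tile of a target-class image
positive (top-level diagnosis propagation) and every control-image tile
control, then fits a classifier on these noisy labels.  Stage 2 keeps only
the positive tiles whose stage-1 inferred target-class probability reaches
the filtering threshold t (default 0.5) — control tiles are never filtered
— and retrains from a fresh initialization.  Exactly two stages, one
filtering round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    ArchitectureSpec,
    TileClassifier,
    TrainConfig,
    TrainingHistory,
    build_model,
    predict_tiles,
    train,
)
from .datatypes import CohortDataset
from .tiling import (
    DEFAULT_TILE_SIZE,
    LABEL_CONTROL,
    LABEL_POSITIVE,
    Tile,
    TileDataset,
    split_into_tiles,
)

DEFAULT_FILTERING_THRESHOLD = 0.5


class EmptySelectionError(RuntimeError):
    """No positive tile survived confidence filtering."""


@dataclass
class WslConfig:
    filtering_threshold: float = DEFAULT_FILTERING_THRESHOLD
    stage1_config: TrainConfig = field(default_factory=TrainConfig)
    stage2_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.filtering_threshold <= 1.0:
            raise ValueError("filtering_threshold must lie in [0, 1]")


@dataclass
class WslReport:
    """Per-stage bookkeeping of the two-stage procedure."""

    threshold: float
    n_weak_positive: int
    n_surviving_positive: int
    n_controls: int
    kept_tiles: list[Tile]
    discarded_tiles: list[Tile]
    stage1_history: TrainingHistory | None = None
    stage2_history: TrainingHistory | None = None
    stage1_model: TileClassifier | None = None
    weak_dataset: TileDataset | None = None

    @property
    def survival_rate(self) -> float:
        return self.n_surviving_positive / self.n_weak_positive


def weak_label_tiles(
    cohort: CohortDataset,
    target_class: str,
    magnification: str,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
    split: str | None = None,
) -> TileDataset:
    """Tile dataset labeled only by top-level diagnosis; masks are not used."""
    tiles: list[Tile] = []
    target_images = cohort.subset(split=split, diagnosis=target_class, magnification=magnification)
    if not target_images:
        raise ValueError(f"no {target_class} images at {magnification}")
    for image in target_images:
        for tile in split_into_tiles(image, tile_size, stride):
            tile.label = LABEL_POSITIVE  # tumor_fraction stays unknown
            tiles.append(tile)
    for image in cohort.subset(split=split, magnification=magnification):
        if image.diagnosis == target_class:
            continue
        for tile in split_into_tiles(image, tile_size, stride):
            tile.label = LABEL_CONTROL
            tiles.append(tile)
    return TileDataset(tiles=tiles, target_class=target_class, magnification=magnification)


def select_confident_tiles(
    stage1_model: TileClassifier,
    weak_dataset: TileDataset,
    t: float = DEFAULT_FILTERING_THRESHOLD,
) -> tuple[TileDataset, WslReport]:
    """Keep positive tiles with stage-1 target probability >= t; controls untouched."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    positives = weak_dataset.subset(LABEL_POSITIVE)
    controls = weak_dataset.subset(LABEL_CONTROL)
    if not positives:
        raise ValueError("weak dataset has no positive tiles")
    probs = predict_tiles(stage1_model, positives)
    p_target = probs[:, stage1_model.class_index(LABEL_POSITIVE)]
    kept = [tile for tile, p in zip(positives, p_target) if p >= t]
    discarded = [tile for tile, p in zip(positives, p_target) if p < t]
    if not kept:
        raise EmptySelectionError(
            f"no positive tile reached the filtering threshold t={t}"
        )
    filtered = TileDataset(
        tiles=kept + controls,
        target_class=weak_dataset.target_class,
        magnification=weak_dataset.magnification,
    )
    report = WslReport(
        threshold=t,
        n_weak_positive=len(positives),
        n_surviving_positive=len(kept),
        n_controls=len(controls),
        kept_tiles=kept,
        discarded_tiles=discarded,
    )
    return filtered, report


def train_wsl(
    cohort: CohortDataset,
    target_class: str,
    magnification: str,
    config: WslConfig,
    arch_spec: ArchitectureSpec | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
    split: str | None = None,
    seed: int = 0,
) -> tuple[TileClassifier, WslReport]:
    """Run the full two-stage procedure and return the stage-2 model.

    Stage 2 reinitializes from scratch rather than continuing stage-1
    weights, avoiding confirmation bias from the noisy first fit.
    """
    arch_spec = arch_spec or ArchitectureSpec()
    weak = weak_label_tiles(cohort, target_class, magnification, tile_size, stride, split)
    stage1 = build_model(arch_spec, seed=seed)
    stage1, hist1 = train(stage1, weak, config.stage1_config)
    filtered, report = select_confident_tiles(stage1, weak, config.filtering_threshold)
    stage2 = build_model(arch_spec, seed=seed + 1)
    stage2, hist2 = train(stage2, filtered, config.stage2_config)
    report.stage1_history = hist1
    report.stage2_history = hist2
    report.stage1_model = stage1
    report.weak_dataset = weak
    return stage2, report


def true_fraction_of_tiles(tiles: list[Tile], cohort: CohortDataset) -> np.ndarray:
    """Recompute each tile's true tumor fraction from held-back cohort masks."""
    from .tiling import tile_tumor_fraction

    out = np.empty(len(tiles))
    for i, tile in enumerate(tiles):
        mask = cohort.masks.get(tile.image_id)
        if mask is None:
            raise KeyError(f"no mask for image {tile.image_id!r}")
        out[i] = tile_tumor_fraction(mask, tile.origin, tile.size)
    return out
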