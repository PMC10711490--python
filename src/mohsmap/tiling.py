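"""Tile extraction and tumor-area labeling.

Images are split into fixed-size square tiles on a regular grid
(0-based, row-major, half-open windows ``[r, r+size) x [c, c+size)``).
When the stride does not divide the image, one extra origin per axis is
snapped to ``dim - size`` so border content is tiled exactly once more
(overlapping the previous tile) instead of being discarded — margins
matter for surgical margin assessment.

A tile is labeled ``positive`` when tumor occupies at least 10% of its
area (inclusive boundary), otherwise ``control``.  Tiles from images of
other diagnoses may be added as extra controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CohortDataset, SpecimenImage, TumorMask

DEFAULT_TILE_SIZE = 224
POSITIVE_TILE_THRESHOLD = 0.10

LABEL_POSITIVE = "positive"
LABEL_CONTROL = "control"
LABEL_UNLABELED = "unlabeled"


@dataclass
class Tile:
    """A square crop with grid origin, provenance and (optionally) a label.

    Pixel content is materialized lazily: ``pixels`` is a view into the
    source image read at access time.
    """

    row: int
    col: int
    size: int
    image_id: str
    patient_id: str
    tumor_fraction: float | None = None
    label: str = LABEL_UNLABELED
    source: np.ndarray | None = field(default=None, repr=False)

    @property
    def pixels(self) -> np.ndarray:
        if self.source is None:
            raise ValueError(f"tile {self.image_id}:({self.row},{self.col}) has no source image")
        return self.source[self.row : self.row + self.size, self.col : self.col + self.size]

    @property
    def origin(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class TileDataset:
    """A labeled tile collection for one target class and magnification."""

    tiles: list[Tile]
    target_class: str
    magnification: str

    def __len__(self) -> int:
        return len(self.tiles)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.tiles:
            counts[t.label] = counts.get(t.label, 0) + 1
        return counts

    def subset(self, label: str) -> list[Tile]:
        return [t for t in self.tiles if t.label == label]


def grid_origins(dim: int, size: int, stride: int) -> list[int]:
    """Window origins along one axis: regular stride plus a border-snapped last origin."""
    if size > dim:
        raise ValueError(f"tile size {size} exceeds image dimension {dim}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    origins = list(range(0, dim - size + 1, stride))
    if origins[-1] != dim - size:
        origins.append(dim - size)
    return origins


def split_into_tiles(
    image: SpecimenImage,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
) -> list[Tile]:
    """Row-major tiles over the edge-snapped grid of ``image``."""
    stride = tile_size if stride is None else stride
    rows = grid_origins(image.height, tile_size, stride)
    cols = grid_origins(image.width, tile_size, stride)
    return [
        Tile(
            row=r,
            col=c,
            size=tile_size,
            image_id=image.image_id,
            patient_id=image.patient_id,
            source=image.pixels,
        )
        for r in rows
        for c in cols
    ]


def tile_tumor_fraction(mask: TumorMask, origin: tuple[int, int], size: int) -> float:
    """Mean mask value over the half-open window at ``origin``."""
    r, c = origin
    h, w = mask.shape
    if r < 0 or c < 0 or r + size > h or c + size > w:
        raise ValueError(f"window {origin} + {size} out of mask bounds {(h, w)}")
    return float(mask.mask[r : r + size, c : c + size].mean())


def label_tile(tumor_fraction: float, positive_threshold: float = POSITIVE_TILE_THRESHOLD) -> str:
    """``positive`` iff tumor occupies at least the threshold fraction (inclusive)."""
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError(f"tumor_fraction must lie in [0, 1], got {tumor_fraction}")
    return LABEL_POSITIVE if tumor_fraction >= positive_threshold else LABEL_CONTROL


def build_training_set(
    cohort: CohortDataset,
    target_class: str,
    magnification: str,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
    include_extra_controls: bool = True,
    positive_threshold: float = POSITIVE_TILE_THRESHOLD,
    split: str | None = None,
) -> TileDataset:
    """Fully supervised tile dataset from annotated target-class images.

    Tiles of annotated target-class images are labeled by their tumor-area
    fraction; with ``include_extra_controls``, every tile of every
    other-diagnosis image (other tumor types, distractors, normal skin) is
    added as a control regardless of annotation.
    """
    tiles: list[Tile] = []
    target_images = cohort.subset(
        split=split, diagnosis=target_class, magnification=magnification, annotated=True
    )
    if not target_images:
        raise ValueError(
            f"no annotated {target_class} images at {magnification}"
            + (f" in split {split!r}" if split else "")
        )
    for image in target_images:
        mask = cohort.masks[image.image_id]
        for tile in split_into_tiles(image, tile_size, stride):
            tile.tumor_fraction = tile_tumor_fraction(mask, tile.origin, tile.size)
            tile.label = label_tile(tile.tumor_fraction, positive_threshold)
            tiles.append(tile)
    if include_extra_controls:
        for image in cohort.subset(split=split, magnification=magnification):
            if image.diagnosis == target_class:
                continue
            for tile in split_into_tiles(image, tile_size, stride):
                tile.label = LABEL_CONTROL
                tiles.append(tile)
    return TileDataset(tiles=tiles, target_class=target_class, magnification=magnification)
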