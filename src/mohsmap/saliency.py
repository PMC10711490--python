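"""Sliding-window inference assembling per-tile probabilities into a map.

Overlapping tile windows are classified and their target-class
probabilities aggregated onto a prediction grid of stride-by-stride cells
anchored at the image origin: a window's probability is credited to every
cell it fully covers, and overlapping contributions are combined by
arithmetic mean (or max).  Overlap smooths the predicted contours and
reduces omissions at tile boundaries.  Includes the cross-magnification
path (e.g., rescaling a 40x image by 2.5 for a 100x model) and a heat-map
overlay renderer for visual QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .classifier import TileClassifier, predict_tiles
from .datatypes import SpecimenImage, TumorMask
from .tiling import DEFAULT_TILE_SIZE, LABEL_POSITIVE, split_into_tiles

MAGNIFICATION_VALUE = {"40x": 40.0, "100x": 100.0}


@dataclass
class GridSpec:
    """Geometry of the prediction grid: stride-sized cells anchored at (0, 0).

    The last row/column of cells may be truncated at the image border, so
    every image pixel belongs to exactly one cell.
    """

    tile_size: int
    stride: int
    image_height: int
    image_width: int

    def __post_init__(self) -> None:
        if self.stride < 1 or self.stride > self.tile_size:
            raise ValueError("stride must satisfy 1 <= stride <= tile_size")

    @property
    def cell_size(self) -> int:
        return self.stride

    @property
    def n_rows(self) -> int:
        return -(-self.image_height // self.stride)

    @property
    def n_cols(self) -> int:
        return -(-self.image_width // self.stride)

    def cell_bounds(self, r: int, c: int) -> tuple[int, int, int, int]:
        """Pixel block (r0, r1, c0, c1) of cell (r, c), truncated at the border."""
        r0, c0 = r * self.stride, c * self.stride
        return (
            r0,
            min(r0 + self.stride, self.image_height),
            c0,
            min(c0 + self.stride, self.image_width),
        )

    def cells_covered_by(self, row: int, col: int, size: int) -> tuple[range, range]:
        """Index ranges of cells whose pixel block lies fully inside the window."""
        r_first = -(-row // self.stride)
        c_first = -(-col // self.stride)
        r_idx = [
            r
            for r in range(r_first, self.n_rows)
            if min((r + 1) * self.stride, self.image_height) <= row + size
        ]
        c_idx = [
            c
            for c in range(c_first, self.n_cols)
            if min((c + 1) * self.stride, self.image_width) <= col + size
        ]
        return r_idx, c_idx


@dataclass
class ProbabilityMap:
    """Per-cell tumor probabilities with coverage multiplicity."""

    grid: GridSpec
    values: np.ndarray  # (n_rows, n_cols) in [0, 1]
    contributing_counts: np.ndarray  # (n_rows, n_cols) int >= 1
    model_magnification: str | None = None
    image_magnification: str | None = None

    def __post_init__(self) -> None:
        expected = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected or self.contributing_counts.shape != expected:
            raise ValueError(f"map arrays must have shape {expected}")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("map values must lie in [0, 1]")
        if (self.contributing_counts < 1).any():
            raise ValueError("every cell must receive at least one prediction")


def sliding_window_probability_map(
    model: TileClassifier,
    image: SpecimenImage,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
    aggregation: str = "mean",
    target_label: str = LABEL_POSITIVE,
) -> ProbabilityMap:
    """Classify every edge-snapped tile window and assemble the saliency map."""
    stride = tile_size // 2 if stride is None else stride
    if tile_size > min(image.height, image.width):
        raise ValueError(f"tile size {tile_size} exceeds image {image.height}x{image.width}")
    if aggregation not in ("mean", "max"):
        raise ValueError("aggregation must be 'mean' or 'max'")
    grid = GridSpec(
        tile_size=tile_size,
        stride=stride,
        image_height=image.height,
        image_width=image.width,
    )
    tiles = split_into_tiles(image, tile_size, stride)
    probs = predict_tiles(model, tiles)[:, model.class_index(target_label)]

    shape = (grid.n_rows, grid.n_cols)
    counts = np.zeros(shape, dtype=int)
    if aggregation == "mean":
        acc = np.zeros(shape)
    else:
        acc = np.full(shape, -np.inf)
    for tile, p in zip(tiles, probs):
        r_idx, c_idx = grid.cells_covered_by(tile.row, tile.col, tile.size)
        rr = np.ix_(r_idx, c_idx)
        counts[rr] += 1
        if aggregation == "mean":
            acc[rr] += p
        else:
            acc[rr] = np.maximum(acc[rr], p)
    if (counts < 1).any():
        raise RuntimeError("coverage gap: some grid cell received no prediction")
    values = acc / counts if aggregation == "mean" else acc
    return ProbabilityMap(
        grid=grid,
        values=np.clip(values, 0.0, 1.0),
        contributing_counts=counts,
        model_magnification=None,
        image_magnification=image.magnification,
    )


def resize_for_cross_magnification(
    image: SpecimenImage,
    target_mag: str,
    mask: TumorMask | None = None,
):
    """Rescale an image (bicubic) and its mask (nearest-neighbor) to another
    magnification, e.g. 40x -> 100x multiplies both dimensions by 2.5."""
    source_mag = image.magnification
    if source_mag not in MAGNIFICATION_VALUE or target_mag not in MAGNIFICATION_VALUE:
        raise ValueError(f"unknown magnification pair ({source_mag!r}, {target_mag!r})")
    factor = MAGNIFICATION_VALUE[target_mag] / MAGNIFICATION_VALUE[source_mag]
    if factor == 1.0:
        out_img = SpecimenImage(
            pixels=image.pixels.copy(),
            patient_id=image.patient_id,
            image_id=image.image_id,
            magnification=target_mag,
            diagnosis=image.diagnosis,
        )
        out_mask = TumorMask(mask=mask.mask.copy()) if mask is not None else None
    else:
        new_shape = (round(image.height * factor), round(image.width * factor))
        resized = _sk_resize(
            image.pixels.astype(float),
            (*new_shape, 3),
            order=3,
            anti_aliasing=factor < 1,
            preserve_range=True,
        )
        out_img = SpecimenImage(
            pixels=np.clip(resized, 0, 255).astype(np.uint8),
            patient_id=image.patient_id,
            image_id=image.image_id,
            magnification=target_mag,
            diagnosis=image.diagnosis,
        )
        out_mask = None
        if mask is not None:
            m = _sk_resize(
                mask.mask.astype(float), new_shape, order=0, anti_aliasing=False,
                preserve_range=True,
            )
            out_mask = TumorMask(mask=m > 0.5)
    return out_img if mask is None else (out_img, out_mask)


def render_overlay(
    pmap: ProbabilityMap,
    image: SpecimenImage,
    colormap: str = "inferno",
    alpha: float = 0.4,
) -> np.ndarray:
    """Pixel-resolution heat-map overlay (visual QC only; never used by metrics)."""
    from matplotlib import colormaps

    g = pmap.grid
    if (g.image_height, g.image_width) != (image.height, image.width):
        raise ValueError("probability map geometry does not match the image")
    if alpha == 0:
        return image.pixels.copy()
    up = np.repeat(np.repeat(pmap.values, g.stride, axis=0), g.stride, axis=1)
    up = up[: image.height, : image.width]
    heat = colormaps[colormap](up)[..., :3] * 255.0
    out = (1 - alpha) * image.pixels.astype(float) + alpha * heat
    return np.clip(out, 0, 255).astype(np.uint8)
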