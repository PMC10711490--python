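"""Pixel-level scoring of probability maps against expert masks.

The ground-truth mask is first reshaped to the same prediction grid the
model produced (each cell's tumor fraction is the mean mask value over its
pixel block, binarized at a majority threshold), then cells are flattened
into score/label sequences and scored with:

* AUPRC — step-wise average precision across all prediction thresholds
  (the primary metric);
* AUROC — rank probability that a positive cell outscores a negative one;
* highest Dice coefficient over a threshold sweep;
* folds enrichment of precision (FEP) — AUPRC divided by the proportion of
  positive cells, the precision gain over a random locator.

An image is eligible for evaluation when at least 10% of its grid is
non-tumor (and at least one cell is tumor, without which the metrics are
undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datatypes import TumorMask
from .saliency import GridSpec, ProbabilityMap

CELL_POSITIVE_THRESHOLD = 0.5
MIN_NEGATIVE_FRACTION = 0.10


@dataclass
class GridMask:
    """Ground truth reshaped onto a prediction grid."""

    grid: GridSpec
    labels: np.ndarray  # (n_rows, n_cols) bool
    cell_tumor_fractions: np.ndarray  # (n_rows, n_cols) float

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean())


@dataclass
class ImageEvalResult:
    """Per-image metric bundle; fep * positive_fraction == auprc exactly."""

    auprc: float
    auroc: float
    dice_max: float
    dice_argmax_threshold: float
    fep: float
    positive_fraction: float
    eligible: bool
    image_id: str | None = None


def reshape_mask_to_grid(
    mask: TumorMask,
    grid: GridSpec,
    cell_positive_threshold: float = CELL_POSITIVE_THRESHOLD,
) -> GridMask:
    """Downsample a pixel mask to the grid: per-cell mean, majority-binarized."""
    if mask.shape != (grid.image_height, grid.image_width):
        raise ValueError(
            f"mask shape {mask.shape} does not match grid image "
            f"{(grid.image_height, grid.image_width)}"
        )
    fractions = np.empty((grid.n_rows, grid.n_cols))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            r0, r1, c0, c1 = grid.cell_bounds(r, c)
            fractions[r, c] = mask.mask[r0:r1, c0:c1].mean()
    return GridMask(
        grid=grid,
        labels=fractions >= cell_positive_threshold,
        cell_tumor_fractions=fractions,
    )


def _as_arrays(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    return s, y


def average_precision(scores, labels) -> float:
    """Step-wise average precision; equal scores collapse to one threshold."""
    s, y = _as_arrays(scores, labels)
    if not y.any():
        raise ValueError("average precision is undefined without positive labels")
    return float(average_precision_score(y, s))


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties count 1/2)."""
    s, y = _as_arrays(scores, labels)
    if y.all() or not y.any():
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(y, s))


def best_dice(scores, labels, threshold_grid=None) -> tuple[float, float]:
    """Maximum Dice over thresholds (prediction = score >= t).

    Defaults to the exact sweep over all distinct score values plus {0, 1};
    falls back to 101 evenly spaced thresholds for very large grids.
    Returns the maximum and the smallest threshold achieving it.
    """
    s, y = _as_arrays(scores, labels)
    if not y.any():
        raise ValueError("Dice is undefined without positive labels")
    if threshold_grid is None:
        distinct = np.unique(s)
        if distinct.size > 5000:
            threshold_grid = np.linspace(0.0, 1.0, 101)
        else:
            threshold_grid = np.union1d(distinct, [0.0, 1.0])
    thresholds = np.sort(np.asarray(threshold_grid, dtype=float))
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    pred = s[None, :] >= thresholds[:, None]  # (T, n)
    tp = (pred & y[None, :]).sum(axis=1)
    fp = (pred & ~y[None, :]).sum(axis=1)
    fn = (~pred & y[None, :]).sum(axis=1)
    denom = 2 * tp + fp + fn
    dice = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = dice.max()
    argmax = thresholds[np.flatnonzero(dice == best)[0]]
    return float(best), float(argmax)


def folds_enrichment(auprc_value: float, positive_fraction: float) -> float:
    """AUPRC divided by the positive proportion — the gain over random localization."""
    if positive_fraction <= 0:
        raise ValueError("folds enrichment is undefined for zero positive fraction")
    return auprc_value / positive_fraction


def image_eligible(
    grid_mask: GridMask, min_negative_fraction: float = MIN_NEGATIVE_FRACTION
) -> bool:
    """Eligible iff >= 10% of cells are non-tumor and at least one cell is tumor.

    The negative fraction is computed directly from cell counts so the
    inclusive >= 10% boundary is exact (1 - positive_fraction would round).
    """
    negative_fraction = float((~grid_mask.labels).mean())
    return negative_fraction >= min_negative_fraction and grid_mask.labels.any()


def evaluate_image(
    pmap: ProbabilityMap,
    mask: TumorMask,
    cell_positive_threshold: float = CELL_POSITIVE_THRESHOLD,
    min_negative_fraction: float = MIN_NEGATIVE_FRACTION,
    image_id: str | None = None,
) -> ImageEvalResult:
    """Score one probability map against its mask on the prediction grid."""
    gm = reshape_mask_to_grid(mask, pmap.grid, cell_positive_threshold)
    scores = pmap.values.ravel()
    labels = gm.labels.ravel()
    pf = float(labels.mean())
    if pf == 0.0:
        raise ValueError("no positive grid cell: metrics undefined for this image")
    ap = average_precision(scores, labels)
    roc = auroc(scores, labels) if not labels.all() else 1.0
    dmax, dthr = best_dice(scores, labels)
    return ImageEvalResult(
        auprc=ap,
        auroc=roc,
        dice_max=dmax,
        dice_argmax_threshold=dthr,
        fep=folds_enrichment(ap, pf),
        positive_fraction=pf,
        eligible=image_eligible(gm, min_negative_fraction),
        image_id=image_id,
    )
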