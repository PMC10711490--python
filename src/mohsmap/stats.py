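"""Patient-level cross-validation, bootstrap CIs, paired tests, agreement.

Summary statistics (by default the across-image median of a metric) get
percentile confidence intervals from ordinary bootstrap resampling with
10,000 iterations.  Models are compared on the same images with the paired
Wilcoxon signed-rank test at a type I error rate of 0.01.  Interrater
agreement between segmentation masks is Fleiss' kappa on 50 x 50 px tiles
binarized at >= 5% tumor fraction.  Cross-validation folds are
leave-one-out at the patient level: each test fold holds all images of
exactly one annotated patient, preventing per-patient information leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .datatypes import CohortDataset, TumorMask
from .tiling import grid_origins

KAPPA_TILE_SIZE = 50
KAPPA_TUMOR_THRESHOLD = 0.05
DEFAULT_BOOTSTRAP_ITERATIONS = 10_000
ALPHA = 0.01


class DegenerateDataError(ValueError):
    """The requested statistic is undefined on this input (e.g. all-zero
    paired differences, or single-category agreement data)."""


@dataclass
class FoldSpec:
    fold_id: int
    test_patient_ids: tuple[str, ...]
    train_patient_ids: tuple[str, ...]


@dataclass
class BootstrapResult:
    statistic_name: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_iterations: int
    level: float
    seed: int | None


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    median_difference: float
    n_effective: int

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p_value < alpha


def default_image_eligibility(cohort: CohortDataset, image_id: str,
                              min_negative_fraction: float = 0.10) -> bool:
    """Annotated, with tumor present and >= 10% non-tumor area (pixel level)."""
    mask = cohort.masks.get(image_id)
    if mask is None:
        return False
    pf = mask.positive_fraction
    return pf > 0.0 and (1.0 - pf) >= min_negative_fraction


def patient_loocv_folds(
    cohort: CohortDataset,
    eligibility: Callable[[CohortDataset, str], bool] | None = None,
) -> list[FoldSpec]:
    """One fold per eligible patient, sorted by patient id.

    A patient is eligible when at least one of their images is annotated
    and metric-eligible; patients without annotations never appear as test
    patients.  Training patients are all other eligible-or-annotated
    patients (anyone with annotated images).
    """
    eligibility = eligibility or default_image_eligibility
    eligible_patients = sorted(
        {
            im.patient_id
            for im in cohort.images
            if eligibility(cohort, im.image_id)
        }
    )
    if len(eligible_patients) < 2:
        raise ValueError(f"LOOCV requires >= 2 eligible patients, found {len(eligible_patients)}")
    annotated_patients = sorted(
        {im.patient_id for im in cohort.images if im.image_id in cohort.masks}
    )
    folds = []
    for i, pid in enumerate(eligible_patients):
        folds.append(
            FoldSpec(
                fold_id=i,
                test_patient_ids=(pid,),
                train_patient_ids=tuple(p for p in annotated_patients if p != pid),
            )
        )
    return folds


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[..., float] = np.median,
    n_iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapResult:
    """Percentile CI of a statistic under ordinary (case) resampling."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("bootstrap requires a non-empty sample")
    rng = np.random.default_rng(seed)
    n = vals.size
    idx = rng.integers(0, n, size=(n_iterations, n))
    resampled = vals[idx]
    try:
        stats = np.asarray(statistic(resampled, axis=1), dtype=float)
    except TypeError:
        stats = np.array([statistic(row) for row in resampled], dtype=float)
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return BootstrapResult(
        statistic_name=getattr(statistic, "__name__", "statistic"),
        point_estimate=float(statistic(vals)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iterations,
        level=level,
        seed=seed,
    )


def paired_wilcoxon(metric_a: Sequence[float], metric_b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-image differences.

    Zero differences are dropped (Wilcoxon's original treatment); ties are
    mid-ranked; the exact null distribution is used for small samples and
    the normal approximation with continuity correction otherwise.  The
    median paired difference (zeros included) is reported alongside.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metrics must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateDataError("all paired differences are zero; no test possible")
    method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=True, method=method)
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=float(np.median(d)),
        n_effective=int(nz.size),
    )


def _tile_rater_labels(
    mask: np.ndarray, tile_size: int, tumor_threshold: float
) -> np.ndarray:
    """Binarize one rater's mask on the edge-snapped tile grid."""
    h, w = mask.shape
    rows = grid_origins(h, tile_size, tile_size)
    cols = grid_origins(w, tile_size, tile_size)
    out = np.empty(len(rows) * len(cols), dtype=bool)
    k = 0
    for r in rows:
        for c in cols:
            frac = mask[r : r + tile_size, c : c + tile_size].mean()
            out[k] = frac >= tumor_threshold
            k += 1
    return out


def fleiss_kappa_masks(
    masks_by_rater: dict[str, list[TumorMask | np.ndarray]],
    tile_size: int = KAPPA_TILE_SIZE,
    tumor_threshold: float = KAPPA_TUMOR_THRESHOLD,
    mode: str = "pooled",
) -> float:
    """Fleiss' kappa for tumor-presence agreement between raters' masks.

    Each rater's mask is tiled into ``tile_size`` squares (edge-snapped)
    and each tile labeled tumor when tumor occupies >= ``tumor_threshold``
    of its area (inclusive).  Items are tiles, categories {tumor,
    non-tumor}, raters the masks.  ``mode='pooled'`` pools tiles across all
    provided images into one item list; ``mode='per_image'`` averages
    per-image kappa values.
    """
    raters = sorted(masks_by_rater)
    if len(raters) < 2:
        raise ValueError("Fleiss' kappa requires >= 2 raters")
    n_images = {len(masks_by_rater[r]) for r in raters}
    if len(n_images) != 1:
        raise ValueError("all raters must annotate the same images")
    n_images = n_images.pop()
    if n_images == 0:
        raise ValueError("no masks provided")

    def as_array(m):
        return m.mask if isinstance(m, TumorMask) else np.asarray(m) > 0

    per_image_labels: list[np.ndarray] = []  # (n_raters, n_tiles) per image
    for i in range(n_images):
        shapes = {as_array(masks_by_rater[r][i]).shape for r in raters}
        if len(shapes) != 1:
            raise ValueError(f"raters disagree on mask geometry for image {i}")
        labels = np.stack(
            [
                _tile_rater_labels(as_array(masks_by_rater[r][i]), tile_size, tumor_threshold)
                for r in raters
            ]
        )
        per_image_labels.append(labels)

    def kappa_from_labels(labels: np.ndarray) -> float:
        n_raters, n_tiles = labels.shape
        if n_tiles < 2:
            raise ValueError("Fleiss' kappa requires >= 2 tiles")
        counts = np.stack([(~labels).sum(axis=0), labels.sum(axis=0)], axis=1)
        if (counts[:, 1] == 0).all() or (counts[:, 0] == 0).all():
            raise DegenerateDataError(
                "all tiles fall in a single category for all raters; kappa undefined"
            )
        return float(_sm_fleiss_kappa(counts, method="fleiss"))

    if mode == "pooled":
        return kappa_from_labels(np.concatenate(per_image_labels, axis=1))
    if mode == "per_image":
        return float(np.mean([kappa_from_labels(lbl) for lbl in per_image_labels]))
    raise ValueError("mode must be 'pooled' or 'per_image'")
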