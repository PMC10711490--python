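"""End-to-end orchestration: simulate -> tile -> train -> predict -> evaluate.

The demo experiment generates a small synthetic cohort (test-scale 448 x 448
images), trains the compact backbone fully supervised on the development
split, runs overlapping sliding-window inference on held-out validation
patients' images and reports per-image metrics with a bootstrap CI of the
median.  A weakly supervised variant and a patient-level LOOCV driver use
the same building blocks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import ArchitectureSpec, TrainConfig, build_model, train
from .datatypes import CohortDataset
from .evaluation import ImageEvalResult, evaluate_image
from .saliency import sliding_window_probability_map
from .stats import bootstrap_ci, patient_loocv_folds
from .synthetic import SynthesisParams, generate_cohort
from .tiling import build_training_set
from .wsl import WslConfig, train_wsl, true_fraction_of_tiles

logger = logging.getLogger("mohsmap")

DEMO_CLASS_MIX = {"BCC": 2 / 3, "SCC": 1 / 6, "normal": 1 / 6}


def demo_run_config(seed: int = 0) -> RunConfig:
    """Pipeline constants for the test-scale demo.

    The demo images are 448 px wide (vs 1600 x 1200 in production), so the
    tile and stride are scaled by the same factor (64 px tiles, 32 px
    inference stride) to preserve the production tile-to-image ratio of
    about 7; all thresholds keep their production values.
    """
    return RunConfig(tile_size=64, inference_stride=32, seed=seed)


@dataclass
class RunConfig:
    """All pipeline constants in one auditable place."""

    tile_size: int = 224
    train_stride: int | None = None  # None -> tile_size (disjoint training tiles)
    inference_stride: int = 112
    tile_positive_threshold: float = 0.10
    wsl_threshold: float = 0.5
    cell_positive_threshold: float = 0.5
    min_negative_fraction: float = 0.10
    kappa_tile_size: int = 50
    kappa_tumor_threshold: float = 0.05
    bootstrap_iterations: int = 10_000
    alpha: float = 0.01
    magnification: str = "100x"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tile_positive_threshold",
            "wsl_threshold",
            "cell_positive_threshold",
            "min_negative_fraction",
            "kappa_tumor_threshold",
            "alpha",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.inference_stride > self.tile_size:
            raise ValueError("inference_stride must not exceed tile_size")


def demo_cohort(
    seed: int = 0,
    n_patients: int = 12,
    images_per_patient: int = 4,
    image_size: int = 448,
    separability: float = 0.9,
    magnification: str = "100x",
) -> CohortDataset:
    """The standard small synthetic cohort used by the demo experiments."""
    params = SynthesisParams(
        image_width=image_size,
        image_height=image_size,
        magnification_tag=magnification,
        separability=separability,
        seed=seed,
    )
    return generate_cohort(
        n_patients=n_patients,
        images_per_patient=images_per_patient,
        class_mix=DEMO_CLASS_MIX,
        params=params,
        seed=seed,
    )


def _evaluate_split(model, cohort, target_class, config: RunConfig, split="validation"):
    """Saliency + metrics for every annotated target-class image in a split."""
    results: list[ImageEvalResult] = []
    for image in cohort.subset(
        split=split, diagnosis=target_class, magnification=config.magnification, annotated=True
    ):
        pmap = sliding_window_probability_map(
            model, image, tile_size=config.tile_size, stride=config.inference_stride
        )
        try:
            res = evaluate_image(
                pmap,
                cohort.masks[image.image_id],
                cell_positive_threshold=config.cell_positive_threshold,
                min_negative_fraction=config.min_negative_fraction,
                image_id=image.image_id,
            )
        except ValueError:
            continue  # no positive grid cell: metrics undefined, image skipped
        if res.eligible:
            results.append(res)
    return results


def _summarize(results: list[ImageEvalResult], config: RunConfig) -> dict:
    arr = {
        name: np.array([getattr(r, name) for r in results])
        for name in ("auprc", "auroc", "dice_max", "fep")
    }
    summary = {f"median_{k}": float(np.median(v)) for k, v in arr.items()}
    summary["n_images"] = len(results)
    if len(results) >= 2:
        ci = bootstrap_ci(
            arr["auprc"], n_iterations=config.bootstrap_iterations, seed=config.seed
        )
        summary["auprc_ci_low"] = ci.ci_low
        summary["auprc_ci_high"] = ci.ci_high
    return summary


def run_demo(
    seed: int = 0,
    out_dir: Path | str | None = None,
    cohort: CohortDataset | None = None,
    target_class: str = "BCC",
    config: RunConfig | None = None,
    arch_spec: ArchitectureSpec | None = None,
    train_config: TrainConfig | None = None,
) -> dict:
    """Full fully-supervised synthetic experiment; returns models and metrics."""
    config = config or demo_run_config(seed)
    cohort = cohort or demo_cohort(seed=seed, magnification=config.magnification)
    arch_spec = arch_spec or ArchitectureSpec()
    train_config = train_config or TrainConfig(
        max_epochs=80, early_stopping_patience=8, seed=seed
    )
    logger.info("demo config: %s", dataclasses.asdict(config))

    dataset = build_training_set(
        cohort,
        target_class,
        config.magnification,
        tile_size=config.tile_size,
        stride=config.train_stride,
        positive_threshold=config.tile_positive_threshold,
        split="development",
    )
    model = build_model(arch_spec, seed=seed)
    model, history = train(model, dataset, train_config)
    results = _evaluate_split(model, cohort, target_class, config)
    if not results:
        raise RuntimeError("no eligible validation image could be evaluated")
    summary = _summarize(results, config)

    out = {
        "cohort": cohort,
        "model": model,
        "history": history,
        "results": results,
        "summary": summary,
        "config": config,
    }
    if out_dir is not None:
        from .io import results_to_dataframe, save_model

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results_to_dataframe(results).to_csv(out_dir / "results.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        (out_dir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2)
        )
        save_model(model, out_dir / "model")
    return out


def run_wsl_experiment(
    seed: int = 0,
    cohort: CohortDataset | None = None,
    target_class: str = "BCC",
    config: RunConfig | None = None,
    arch_spec: ArchitectureSpec | None = None,
    train_config: TrainConfig | None = None,
) -> dict:
    """Two-stage weakly supervised experiment with mask-based enrichment audit.

    The generator's masks are held back from training and used only to
    verify that confidence filtering enriched the surviving positive tiles
    for true tumor content.
    """
    config = config or demo_run_config(seed)
    cohort = cohort or demo_cohort(seed=seed, magnification=config.magnification)
    arch_spec = arch_spec or ArchitectureSpec()
    train_config = train_config or TrainConfig(
        max_epochs=60, early_stopping_patience=8, seed=seed
    )
    wsl_config = WslConfig(
        filtering_threshold=config.wsl_threshold,
        stage1_config=train_config,
        stage2_config=train_config,
    )
    model, report = train_wsl(
        cohort,
        target_class,
        config.magnification,
        wsl_config,
        arch_spec=arch_spec,
        tile_size=config.tile_size,
        stride=config.train_stride,
        split="development",
        seed=seed,
    )
    kept_frac = true_fraction_of_tiles(report.kept_tiles, cohort)
    discarded_frac = (
        true_fraction_of_tiles(report.discarded_tiles, cohort)
        if report.discarded_tiles
        else np.array([])
    )
    enrichment = {
        "mean_true_fraction_kept": float(kept_frac.mean()),
        "mean_true_fraction_discarded": (
            float(discarded_frac.mean()) if discarded_frac.size else float("nan")
        ),
        "survival_rate": report.survival_rate,
    }
    results = _evaluate_split(model, cohort, target_class, config)
    summary = _summarize(results, config) if results else {}
    return {
        "cohort": cohort,
        "model": model,
        "report": report,
        "enrichment": enrichment,
        "results": results,
        "summary": summary,
    }


def _subcohort(cohort: CohortDataset, patient_ids: set[str]) -> CohortDataset:
    images = [im for im in cohort.images if im.patient_id in patient_ids]
    ids = {im.image_id for im in images}
    return CohortDataset(
        images=images,
        masks={k: v for k, v in cohort.masks.items() if k in ids},
        splits={k: v for k, v in cohort.splits.items() if k in ids},
    )


def run_patient_loocv(
    cohort: CohortDataset,
    target_class: str = "BCC",
    config: RunConfig | None = None,
    arch_spec: ArchitectureSpec | None = None,
    train_config: TrainConfig | None = None,
    max_folds: int | None = None,
) -> dict:
    """Patient-level leave-one-out cross-validation over annotated patients."""
    config = config or RunConfig()
    arch_spec = arch_spec or ArchitectureSpec()
    train_config = train_config or TrainConfig(
        max_epochs=40, early_stopping_patience=6, seed=config.seed
    )
    folds = patient_loocv_folds(cohort)
    if max_folds is not None:
        folds = folds[:max_folds]
    all_results: list[ImageEvalResult] = []
    fold_records = []
    for fold in folds:
        train_cohort = _subcohort(cohort, set(fold.train_patient_ids))
        test_cohort = _subcohort(cohort, set(fold.test_patient_ids))
        dataset = build_training_set(
            train_cohort,
            target_class,
            config.magnification,
            tile_size=config.tile_size,
            stride=config.train_stride,
            positive_threshold=config.tile_positive_threshold,
        )
        model = build_model(arch_spec, seed=config.seed + fold.fold_id)
        model, _ = train(model, dataset, train_config)
        results = _evaluate_split(model, test_cohort, target_class, config, split=None)
        all_results.extend(results)
        fold_records.append(
            {"fold_id": fold.fold_id, "test_patient": fold.test_patient_ids[0],
             "n_images": len(results)}
        )
    summary = _summarize(all_results, config) if all_results else {}
    return {"folds": folds, "fold_records": fold_records, "results": all_results,
            "summary": summary}
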