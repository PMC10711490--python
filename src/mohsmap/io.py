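"""File formats: images, masks, manifests, maps, model checkpoints, results.

Images are 8-bit RGB PNG (TIFF accepted on read); masks are single-channel
8-bit PNG with values {0, 255}; cohort and tile manifests are headered CSV;
probability maps are flat CSV (row, col, value, count) with a JSON grid
sidecar; model checkpoints are an .npz weight archive plus a JSON sidecar
describing the architecture and class order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .classifier import ArchitectureSpec, TileClassifier, build_model
from .datatypes import CohortDataset, SpecimenImage, TumorMask
from .evaluation import ImageEvalResult
from .saliency import GridSpec, ProbabilityMap

MANIFEST_COLUMNS = ["image_id", "patient_id", "split", "magnification", "diagnosis", "image_path"]


def write_image(pixels: np.ndarray, path: Path | str) -> None:
    PILImage.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def read_image(path: Path | str) -> np.ndarray:
    return np.asarray(PILImage.open(path).convert("RGB"))


def write_mask(mask: TumorMask, path: Path | str) -> None:
    PILImage.fromarray((mask.mask * np.uint8(255))).save(path)


def read_mask(path: Path | str) -> TumorMask:
    arr = np.asarray(PILImage.open(path).convert("L"))
    return TumorMask(mask=arr > 127)


def write_cohort(cohort: CohortDataset, out_dir: Path | str) -> Path:
    """Write images, masks and the cohort manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for im in cohort.images:
        image_path = out_dir / "images" / f"{im.image_id}.png"
        write_image(im.pixels, image_path)
        mask_path = ""
        if im.image_id in cohort.masks:
            mask_path = str(Path("masks") / f"{im.image_id}.png")
            write_mask(cohort.masks[im.image_id], out_dir / mask_path)
        rows.append(
            {
                "image_id": im.image_id,
                "patient_id": im.patient_id,
                "split": cohort.splits.get(im.image_id, ""),
                "magnification": im.magnification,
                "diagnosis": im.diagnosis,
                "image_path": str(Path("images") / f"{im.image_id}.png"),
                "mask_path": mask_path,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_manifest(path: Path | str) -> CohortDataset:
    """Load and validate a cohort manifest written by :func:`write_cohort`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    dupes = df[df.duplicated("image_id", keep=False)]
    if not dupes.empty:
        rows = ", ".join(f"row {i + 2}: {r.image_id!r}" for i, r in dupes.iterrows())
        raise ValueError(f"duplicate image_id entries in manifest: {rows}")
    base = path.parent
    images, masks, splits = [], {}, {}
    for i, row in df.iterrows():
        image_path = base / row["image_path"]
        if not image_path.exists():
            raise FileNotFoundError(f"row {i + 2}: image file {image_path} does not exist")
        images.append(
            SpecimenImage(
                pixels=read_image(image_path),
                patient_id=row["patient_id"],
                image_id=row["image_id"],
                magnification=row["magnification"],
                diagnosis=row["diagnosis"],
            )
        )
        mask_path = row.get("mask_path", "")
        if mask_path:
            full = base / mask_path
            if not full.exists():
                raise FileNotFoundError(f"row {i + 2}: mask file {full} does not exist")
            masks[row["image_id"]] = read_mask(full)
        if row["split"]:
            splits[row["image_id"]] = row["split"]
    return CohortDataset(images=images, masks=masks, splits=splits)


def write_tile_manifest(dataset, path: Path | str) -> None:
    rows = [
        {
            "image_id": t.image_id,
            "patient_id": t.patient_id,
            "row": t.row,
            "col": t.col,
            "size": t.size,
            "tumor_fraction": "" if t.tumor_fraction is None else t.tumor_fraction,
            "label": t.label,
        }
        for t in dataset.tiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_probability_map(pmap: ProbabilityMap, csv_path: Path | str) -> None:
    csv_path = Path(csv_path)
    g = pmap.grid
    rows, cols = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols), indexing="ij")
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "value": pmap.values.ravel(),
            "count": pmap.contributing_counts.ravel(),
        }
    ).to_csv(csv_path, index=False)
    sidecar = {
        "tile_size": g.tile_size,
        "stride": g.stride,
        "image_height": g.image_height,
        "image_width": g.image_width,
        "model_magnification": pmap.model_magnification,
        "image_magnification": pmap.image_magnification,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_probability_map(csv_path: Path | str) -> ProbabilityMap:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    grid = GridSpec(
        tile_size=meta["tile_size"],
        stride=meta["stride"],
        image_height=meta["image_height"],
        image_width=meta["image_width"],
    )
    df = pd.read_csv(csv_path)
    values = np.zeros((grid.n_rows, grid.n_cols))
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    values[df["row"], df["col"]] = df["value"]
    counts[df["row"], df["col"]] = df["count"]
    return ProbabilityMap(
        grid=grid,
        values=values,
        contributing_counts=counts,
        model_magnification=meta.get("model_magnification"),
        image_magnification=meta.get("image_magnification"),
    )


def save_model(model: TileClassifier, out_dir: Path | str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "weights.npz", **model.net.get_state())
    sidecar = {
        "spec": dataclasses.asdict(model.spec),
        "class_order": list(model.class_order),
        "trained": model.trained,
    }
    (out_dir / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(model_dir: Path | str) -> TileClassifier:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    spec_dict = sidecar["spec"]
    for key in ("dense_layer_widths", "conv_filters"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = ArchitectureSpec(**spec_dict)
    model = build_model(spec, seed=0, class_order=tuple(sidecar["class_order"]))
    with np.load(model_dir / "weights.npz") as npz:
        model.net.set_state({k: npz[k] for k in npz.files})
    model.trained = bool(sidecar["trained"])
    return model


def results_to_dataframe(results: list[ImageEvalResult], **extra) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    for key, value in extra.items():
        df[key] = value
    return df
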