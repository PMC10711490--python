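from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mohsmap.datatypes import CohortDataset, SpecimenImage, TumorMask
from mohsmap.synthetic import SynthesisParams, generate_cohort


class StubModel:
    """Duck-typed classifier whose positive probability is a pure function
    of the (resized) tile pixels — no training, fully deterministic."""

    class _Spec:
        def __init__(self, input_size):
            self.input_size = input_size

    class_order = ("control", "positive")

    def __init__(self, prob_fn, input_size: int = 16):
        self.spec = self._Spec(input_size)
        self.prob_fn = prob_fn

    def class_index(self, label: str) -> int:
        return self.class_order.index(label)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = np.array([float(np.clip(self.prob_fn(tile), 0, 1)) for tile in x])
        return np.stack([1 - p, p], axis=1)


@pytest.fixture
def stub_model_constant():
    def make(p: float, input_size: int = 16) -> StubModel:
        return StubModel(lambda tile: p, input_size=input_size)

    return make


@pytest.fixture
def stub_model_mean():
    """Probability = mean of the resized tile (content-dependent, known to oracles)."""
    return StubModel(lambda tile: float(tile.mean()), input_size=16)


@pytest.fixture(scope="session")
def small_params() -> SynthesisParams:
    return SynthesisParams(
        image_width=160,
        image_height=160,
        blob_radius_range=(20.0, 45.0),
        n_tumor_blobs=2,
        separability=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params) -> CohortDataset:
    """4 patients x 2 images at 160 x 160, mixed diagnoses — for structural tests."""
    return generate_cohort(
        n_patients=4,
        images_per_patient=2,
        class_mix={"BCC": 0.5, "SCC": 0.25, "normal": 0.25},
        params=small_params,
        seed=11,
    )


def make_flat_cohort(
    n_patients: int,
    images_per_patient: int = 2,
    annotated_patients: set[int] | None = None,
    positive_fraction: float = 0.3,
    size: int = 20,
) -> CohortDataset:
    """A structurally valid cohort with trivial pixel content (fast, no rendering)."""
    images, masks, splits = [], {}, {}
    for p in range(n_patients):
        pid = f"P{p:03d}"
        for k in range(images_per_patient):
            image_id = f"{pid}_i{k}"
            images.append(
                SpecimenImage(
                    pixels=np.zeros((size, size, 3), dtype=np.uint8),
                    patient_id=pid,
                    image_id=image_id,
                    magnification="100x",
                    diagnosis="BCC",
                )
            )
            splits[image_id] = "development"
            if annotated_patients is None or p in annotated_patients:
                mask = np.zeros((size, size), dtype=bool)
                n_pos = int(positive_fraction * size * size)
                mask.ravel()[:n_pos] = True
                masks[image_id] = TumorMask(mask=mask)
    return CohortDataset(images=images, masks=masks, splits=splits)
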