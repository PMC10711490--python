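"""Core in-memory containers for the frozen-section analysis pipeline.

A :class:`SpecimenImage` is one focused microscope view (FMV): a single
camera capture of an H&E frozen section at a fixed magnification, carrying
patient provenance and a top-level diagnosis.  A :class:`TumorMask` is the
pixel-aligned binary expert segmentation of tumor within that view, and a
:class:`CohortDataset` bundles images, masks and the patient-level
development/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAGNIFICATIONS = ("40x", "100x")
SPLITS = ("development", "validation")


class CohortError(ValueError):
    """Raised when cohort-level invariants are violated."""


@dataclass
class SpecimenImage:
    """One RGB microscope field-of-view with provenance metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    patient_id: str
    image_id: str
    magnification: str
    diagnosis: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(
                f"magnification must be one of {MAGNIFICATIONS}, got {self.magnification!r}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TumorMask:
    """Binary per-pixel tumor annotation aligned to one SpecimenImage."""

    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")
        if self.mask.dtype != bool:
            uniq = np.unique(self.mask)
            if not np.isin(uniq, (0, 1, 255)).all():
                raise ValueError("mask must be binary (0/1 or 0/255)")
            self.mask = self.mask > 0

    @property
    def positive_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class CohortDataset:
    """A collection of specimens with masks and a patient-level split.

    Invariants enforced on construction: unique image ids, every mask's
    image id present among the images, mask geometry matching its image,
    one patient id per patient, split tags from {development, validation}.
    """

    images: list[SpecimenImage]
    masks: dict[str, TumorMask] = field(default_factory=dict)
    splits: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for im in self.images:
            if im.image_id in seen:
                raise CohortError(f"duplicate image_id {im.image_id!r}")
            seen.add(im.image_id)
        for image_id, mask in self.masks.items():
            if image_id not in seen:
                raise CohortError(f"mask for unknown image_id {image_id!r}")
            im = self.image(image_id)
            if mask.shape != (im.height, im.width):
                raise CohortError(
                    f"mask shape {mask.shape} != image shape "
                    f"{(im.height, im.width)} for {image_id!r}"
                )
        for image_id, tag in self.splits.items():
            if tag not in SPLITS:
                raise CohortError(f"unknown split tag {tag!r} for {image_id!r}")

    def image(self, image_id: str) -> SpecimenImage:
        for im in self.images:
            if im.image_id == image_id:
                return im
        raise KeyError(image_id)

    def patients(self) -> list[str]:
        return sorted({im.patient_id for im in self.images})

    def images_for_patient(self, patient_id: str) -> list[SpecimenImage]:
        return [im for im in self.images if im.patient_id == patient_id]

    def split_of(self, image_id: str) -> str | None:
        return self.splits.get(image_id)

    def subset(
        self,
        *,
        split: str | None = None,
        diagnosis: str | None = None,
        magnification: str | None = None,
        annotated: bool | None = None,
        patient_ids: set[str] | None = None,
    ) -> list[SpecimenImage]:
        """Filter images by split / diagnosis / magnification / annotation."""
        out = []
        for im in self.images:
            if split is not None and self.splits.get(im.image_id) != split:
                continue
            if diagnosis is not None and im.diagnosis != diagnosis:
                continue
            if magnification is not None and im.magnification != magnification:
                continue
            if annotated is not None and (im.image_id in self.masks) != annotated:
                continue
            if patient_ids is not None and im.patient_id not in patient_ids:
                continue
            out.append(im)
        return out
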