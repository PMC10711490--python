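"""Synthetic frozen-section image generator with known tumor geometry.

Real Mohs frozen sections are H&E stained: eosin-pink stroma with scattered
fibroblast nuclei, and tumor nests appearing as dense fields of dark
basaloid (BCC) or keratinizing (SCC) nuclei.  This module emulates that
structure cheaply and controllably:

* the background is a pink colored-noise texture with sparse dark nuclei;
* tumor regions are unions of analytic ellipses ("blobs") re-tinted toward
  the tumor hue and stamped with a dense nucleus field;
* a single ``separability`` parameter in [0, 1] linearly interpolates both
  the tint contrast and the nucleus density, so ``separability = 0`` leaves
  the tumor region rendered by the untouched background process (tumor and
  background are then identically distributed) while ``separability = 1``
  gives well-separated color/texture statistics.

The returned mask is exactly the analytic blob geometry (a pixel is positive
iff its center lies inside a blob), so every downstream stage can be tested
against a known ground truth.  All randomness flows from a single integer
seed through per-image substreams, making outputs order-independent and
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .datatypes import MAGNIFICATIONS, CohortDataset, SpecimenImage, TumorMask

TUMOR_CLASSES = ("BCC", "SCC")
DISTRACTOR_KINDS = ("other_tumor", "follicle_rings", "inflammation_speckle", "plain")

# Diagnosis labels accepted by generate_cohort for non-tumor patients,
# mapped onto the distractor texture used to render their images.
CONTROL_KIND_BY_DIAGNOSIS = {
    "normal": "plain",
    "AK": "follicle_rings",
    "other_tumor": "other_tumor",
    "follicle_rings": "follicle_rings",
    "inflammation_speckle": "inflammation_speckle",
    "plain": "plain",
}

_BG_COLOR = np.array([226.0, 183.0, 197.0])  # eosin-stained stroma
_TUMOR_TINT = {"BCC": np.array([118.0, 88.0, 168.0]), "SCC": np.array([196.0, 122.0, 84.0])}
_NUCLEUS_COLOR = {"BCC": np.array([62.0, 44.0, 118.0]), "SCC": np.array([120.0, 58.0, 48.0])}
_STROMA_NUCLEUS_COLOR = np.array([120.0, 80.0, 140.0])


@dataclass
class SynthesisParams:
    """Knobs of the synthetic specimen generator."""

    image_width: int = 448
    image_height: int = 448
    magnification_tag: str = "100x"
    n_tumor_blobs: int = 3
    blob_radius_range: tuple[float, float] = (55.0, 110.0)
    separability: float = 0.9
    distractor_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.magnification_tag not in MAGNIFICATIONS:
            raise ValueError(f"magnification_tag must be one of {MAGNIFICATIONS}")
        if self.n_tumor_blobs < 0:
            raise ValueError("n_tumor_blobs must be >= 0")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("blob_radius_range must satisfy 0 < min <= max")
        half_diag = 0.5 * float(np.hypot(self.image_width, self.image_height))
        if hi > half_diag:
            raise ValueError(
                f"max blob radius {hi} exceeds image half-diagonal {half_diag:.1f}"
            )
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.distractor_density < 0:
            raise ValueError("distractor_density must be >= 0")


def _image_rng(seed: int, stream: int) -> np.random.Generator:
    # Counter-based substream: per-image outputs are independent of the
    # order in which images are generated.
    return np.random.default_rng([int(seed), int(stream)])


def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Pink stroma: base color + smooth colored noise + fine grain."""
    img = np.broadcast_to(_BG_COLOR, (h, w, 3)).copy()
    coarse = gaussian_filter(rng.standard_normal((h, w, 3)), sigma=(8, 8, 0))
    img += coarse * 60.0
    img += rng.standard_normal((h, w, 3)) * 5.0
    return img


def _stamp_nuclei(
    img: np.ndarray,
    rng: np.random.Generator,
    region: np.ndarray | None,
    n: int,
    color: np.ndarray,
    radius_range: tuple[float, float] = (2.0, 4.0),
) -> None:
    """Stamp ``n`` small dark elliptical nuclei, centers restricted to ``region``."""
    h, w = img.shape[:2]
    if n <= 0:
        return
    if region is None:
        rows = rng.integers(0, h, size=n)
        cols = rng.integers(0, w, size=n)
    else:
        flat = np.flatnonzero(region)
        if flat.size == 0:
            return
        picks = rng.choice(flat, size=n)
        rows, cols = np.unravel_index(picks, (h, w))
    for r, c in zip(rows, cols):
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(r, c, a, b, shape=(h, w), rotation=rot)
        shade = rng.uniform(0.75, 1.0)
        img[rr, cc] = img[rr, cc] * (1 - shade) + color * shade


def _plant_blobs(
    rng: np.random.Generator,
    h: int,
    w: int,
    n_blobs: int,
    radius_range: tuple[float, float],
) -> np.ndarray:
    """Union of random analytic ellipses; pixel positive iff its center is inside."""
    mask = np.zeros((h, w), dtype=bool)
    if n_blobs == 0:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _render(
    rng: np.random.Generator,
    h: int,
    w: int,
    tumor_mask: np.ndarray,
    separability: float,
    tumor_class: str,
) -> np.ndarray:
    """Render background everywhere, then overlay tumor texture inside the mask.

    The overlay strength is proportional to ``separability``; at 0 the tumor
    region is left exactly as the background rendered it.
    """
    img = _background(rng, h, w)
    # Sparse stromal nuclei are part of the background process (present
    # everywhere, including inside blobs, regardless of separability).
    n_stroma = int(0.004 * h * w / 28)
    _stamp_nuclei(img, rng, None, n_stroma, _STROMA_NUCLEUS_COLOR)
    s = float(separability)
    if s > 0 and tumor_mask.any():
        tint = _TUMOR_TINT[tumor_class]
        blend = 0.5 * s
        img[tumor_mask] = img[tumor_mask] * (1 - blend) + tint * blend
        area = int(tumor_mask.sum())
        n_nuclei = int(0.35 * s * area / 28)
        _stamp_nuclei(img, rng, tumor_mask, n_nuclei, _NUCLEUS_COLOR[tumor_class])
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_specimen(
    params: SynthesisParams,
    patient_id: str,
    diagnosis: str = "BCC",
    image_id: str | None = None,
    stream: int = 0,
) -> tuple[SpecimenImage, TumorMask]:
    """Generate one tumor-bearing specimen and its exact ground-truth mask."""
    if diagnosis not in TUMOR_CLASSES:
        raise ValueError(f"diagnosis must be one of {TUMOR_CLASSES}, got {diagnosis!r}")
    rng = _image_rng(params.seed, stream)
    h, w = params.image_height, params.image_width
    mask = _plant_blobs(rng, h, w, params.n_tumor_blobs, params.blob_radius_range)
    pixels = _render(rng, h, w, mask, params.separability, diagnosis)
    image = SpecimenImage(
        pixels=pixels,
        patient_id=patient_id,
        image_id=image_id or f"{patient_id}_img{stream}",
        magnification=params.magnification_tag,
        diagnosis=diagnosis,
    )
    return image, TumorMask(mask=mask)


def generate_control_image(
    kind: str,
    params: SynthesisParams,
    patient_id: str,
    image_id: str | None = None,
    stream: int = 0,
    target_class: str = "BCC",
) -> SpecimenImage:
    """Generate a control image containing no target-class tumor texture.

    ``other_tumor`` plants blobs rendered with the *other* tumor class's
    texture; ``follicle_rings`` draws dark annuli mimicking hair follicles;
    ``inflammation_speckle`` scatters dense tiny dark cells; ``plain`` is
    bare stroma.
    """
    if kind not in DISTRACTOR_KINDS:
        raise ValueError(f"unknown control kind {kind!r}; choose from {DISTRACTOR_KINDS}")
    rng = _image_rng(params.seed, stream)
    h, w = params.image_height, params.image_width
    if kind == "other_tumor":
        other = "SCC" if target_class == "BCC" else "BCC"
        mask = _plant_blobs(rng, h, w, params.n_tumor_blobs, params.blob_radius_range)
        pixels = _render(rng, h, w, mask, params.separability, other)
    else:
        pixels = _render(rng, h, w, np.zeros((h, w), bool), 0.0, target_class)
        img = pixels.astype(float)
        if kind == "follicle_rings":
            n_rings = max(1, int(round(3 * params.distractor_density)))
            for _ in range(n_rings):
                cy, cx = rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)
                r_out = rng.uniform(25, 60)
                ring = np.zeros((h, w), bool)
                rr, cc = draw_ellipse(cy, cx, r_out, r_out, shape=(h, w))
                ring[rr, cc] = True
                rr, cc = draw_ellipse(cy, cx, 0.65 * r_out, 0.65 * r_out, shape=(h, w))
                ring[rr, cc] = False
                img[ring] = img[ring] * 0.35 + _STROMA_NUCLEUS_COLOR * 0.65
        elif kind == "inflammation_speckle":
            n = int(0.01 * h * w * params.distractor_density / 6)
            _stamp_nuclei(img, rng, None, n, np.array([80.0, 60.0, 130.0]), (1.0, 2.0))
        pixels = np.clip(img, 0, 255).astype(np.uint8)
    return SpecimenImage(
        pixels=pixels,
        patient_id=patient_id,
        image_id=image_id or f"{patient_id}_img{stream}",
        magnification=params.magnification_tag,
        diagnosis=kind,
    )


def render_texture_patch(
    size: int,
    separability: float,
    tumor: bool,
    seed: int = 0,
    tumor_class: str = "BCC",
) -> np.ndarray:
    """A square patch of pure tumor or pure background texture (test helper)."""
    rng = np.random.default_rng(seed)
    mask = np.full((size, size), bool(tumor))
    return _render(rng, size, size, mask, separability, tumor_class)


def generate_cohort(
    n_patients: int,
    images_per_patient: int,
    class_mix: dict[str, float],
    params: SynthesisParams,
    seed: int,
    validation_fraction: float = 1 / 3,
) -> CohortDataset:
    """Generate a multi-patient cohort with a patient-level split.

    Each patient carries a single diagnosis drawn from ``class_mix`` and is
    assigned whole to the development or validation split.  The split is
    stratified by diagnosis so both splits contain each diagnosis whenever
    patient counts allow.  Tumor-class images come with ground-truth masks;
    control-class images have none (implicitly all-negative).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_mix must sum to 1, got {probs.sum()}")
    for c in classes:
        if c not in TUMOR_CLASSES and c not in CONTROL_KIND_BY_DIAGNOSIS:
            raise ValueError(f"unknown diagnosis {c!r} in class_mix")

    rng = np.random.default_rng(seed)
    patient_ids = [f"P{i:04d}" for i in range(n_patients)]
    diagnoses = {p: rng.choice(classes, p=probs) for p in patient_ids}

    # Stratified patient-level split.
    split: dict[str, str] = {}
    for diag in classes:
        group = [p for p in patient_ids if diagnoses[p] == diag]
        order = rng.permutation(len(group))
        n_val = int(round(len(group) * validation_fraction))
        if len(group) >= 2:
            n_val = min(max(n_val, 1), len(group) - 1)
        for rank, idx in enumerate(order):
            split[group[idx]] = "validation" if rank < n_val else "development"

    images: list[SpecimenImage] = []
    masks: dict[str, TumorMask] = {}
    splits: dict[str, str] = {}
    stream = 0
    for p in patient_ids:
        diag = str(diagnoses[p])
        for k in range(images_per_patient):
            image_id = f"{p}_img{k}"
            img_params = dataclasses.replace(params, seed=seed)
            if diag in TUMOR_CLASSES:
                image, mask = generate_specimen(
                    img_params, p, diag, image_id=image_id, stream=stream
                )
                masks[image_id] = mask
            else:
                image = generate_control_image(
                    CONTROL_KIND_BY_DIAGNOSIS[diag],
                    img_params,
                    p,
                    image_id=image_id,
                    stream=stream,
                )
                image.diagnosis = diag
            images.append(image)
            splits[image_id] = split[p]
            stream += 1
    return CohortDataset(images=images, masks=masks, splits=splits)
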