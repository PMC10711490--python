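"""Tile classifier: architecture contract, augmentation, and training loop.

The architecture contract mirrors the production design — a convolutional
feature extractor topped by exactly three dense layers and a softmax — with
a compact from-scratch extractor as the built-in backbone (external
pretrained backbones can be registered; none are bundled or downloaded).
Training minimizes categorical cross-entropy with on-the-fly augmentation,
early stopping on a patient-grouped validation split, and a hard cap of
200 epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import GroupShuffleSplit

from .nnet import Adam, SmallConvNet
from .tiling import LABEL_CONTROL, LABEL_POSITIVE, Tile, TileDataset

MAX_EPOCHS_CAP = 200
DEFAULT_CLASS_ORDER = (LABEL_CONTROL, LABEL_POSITIVE)

_BACKBONES: dict[str, object] = {}


def register_backbone(backbone_id: str, factory) -> None:
    """Register a backbone factory: ``factory(spec, rng) -> SmallConvNet-like``."""
    _BACKBONES[backbone_id] = factory


@dataclass
class ArchitectureSpec:
    """Classifier architecture: backbone + three dense layers + softmax."""

    backbone_id: str = "small"
    dense_layer_widths: tuple[int, int, int] = (256, 64, 16)
    n_classes: int = 2
    pretrained: bool = False
    input_size: int = 32  # tiles are resampled to this side length
    conv_filters: tuple[int, int] = (8, 16)

    def __post_init__(self) -> None:
        if len(self.dense_layer_widths) != 3:
            raise ValueError("exactly three dense layers are required before the softmax")
        if any(w <= 0 for w in self.dense_layer_widths):
            raise ValueError("dense layer widths must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class AugmentationSpec:
    """Label-preserving tile augmentation: flips, right-angle rotations, mild jitter."""

    flips: bool = True
    rotations: bool = True
    brightness_delta: float = 0.05
    color_delta: float = 0.03

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        return cls(flips=False, rotations=False, brightness_delta=0.0, color_delta=0.0)


@dataclass
class TrainConfig:
    max_epochs: int = 100
    early_stopping_patience: int = 10
    validation_fraction: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-3
    augmentation_spec: AugmentationSpec = field(default_factory=AugmentationSpec)
    class_balance: bool = True  # inverse-frequency class weights in the loss
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.max_epochs <= MAX_EPOCHS_CAP:
            raise ValueError(f"max_epochs must be in [1, {MAX_EPOCHS_CAP}]")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class TileClassifier:
    """A (possibly trained) tile classifier with a stable class order."""

    spec: ArchitectureSpec
    net: SmallConvNet
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER
    trained: bool = False

    def class_index(self, label: str) -> int:
        return self.class_order.index(label)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(x)


def build_model(
    spec: ArchitectureSpec,
    seed: int = 0,
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER,
    initial_weights: dict[str, np.ndarray] | None = None,
) -> TileClassifier:
    """Initialize a classifier; deterministic given ``seed`` unless pretrained."""
    if len(class_order) != spec.n_classes:
        raise ValueError("class_order length must equal n_classes")
    rng = np.random.default_rng(seed)
    if spec.backbone_id == "small":
        net = SmallConvNet(
            spec.input_size, spec.dense_layer_widths, spec.n_classes, rng, spec.conv_filters
        )
    elif spec.backbone_id in _BACKBONES:
        net = _BACKBONES[spec.backbone_id](spec, rng)
    else:
        raise ValueError(
            f"unknown backbone_id {spec.backbone_id!r}: only 'small' is built in; "
            "register external backbones with register_backbone()"
        )
    if spec.pretrained:
        if initial_weights is None:
            raise ValueError("pretrained=True requires externally supplied initial_weights")
        net.set_state(initial_weights)
    return TileClassifier(spec=spec, net=net, class_order=tuple(class_order))


def augment_tile(
    pixels: np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """One random label-preserving transform of a square RGB tile in [0, 1]."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = np.asarray(pixels, dtype=float)
    ops = [lambda a: a]
    if spec.flips:
        ops += [lambda a: a[:, ::-1], lambda a: a[::-1, :]]
    if spec.rotations:
        ops += [lambda a: np.rot90(a, k) for k in (1, 2, 3)]
    out = ops[rng.integers(len(ops))](out)
    if spec.brightness_delta > 0 or spec.color_delta > 0:
        shift = rng.uniform(-spec.brightness_delta, spec.brightness_delta)
        channel = rng.uniform(-spec.color_delta, spec.color_delta, size=3)
        out = np.clip(out + shift + channel, 0.0, 1.0)
    return np.ascontiguousarray(out)


def prepare_tile_pixels(pixel_arrays: list[np.ndarray], input_size: int) -> np.ndarray:
    """Stack raw uint8 tiles into the model's input tensor (resampled, [0, 1])."""
    out = np.empty((len(pixel_arrays), input_size, input_size, 3))
    for i, p in enumerate(pixel_arrays):
        a = np.asarray(p, dtype=float) / 255.0
        if a.shape[:2] != (input_size, input_size):
            a = _sk_resize(a, (input_size, input_size, 3), anti_aliasing=True)
        out[i] = a
    return out


def _dataset_arrays(model: TileClassifier, tiles: list[Tile]):
    x = prepare_tile_pixels([t.pixels for t in tiles], model.spec.input_size)
    y = np.array([model.class_index(t.label) for t in tiles])
    groups = np.array([t.patient_id for t in tiles])
    return x, y, groups


def train(
    model: TileClassifier,
    dataset: TileDataset,
    config: TrainConfig,
) -> tuple[TileClassifier, TrainingHistory]:
    """Fit the classifier on labeled tiles with early stopping.

    The internal validation split is grouped by patient (no patient appears
    on both sides).  Training stops when the validation loss has not
    improved for ``early_stopping_patience`` epochs or at ``max_epochs``,
    whichever comes first, and the best-validation-loss weights are
    restored.
    """
    tiles = [t for t in dataset.tiles if t.label in model.class_order]
    if not tiles:
        raise ValueError("empty dataset")
    labels = {t.label for t in tiles}
    if len(labels) < 2:
        raise ValueError(f"training requires >= 2 classes, found {sorted(labels)}")

    x, y, groups = _dataset_arrays(model, tiles)
    if len(np.unique(groups)) < 2:
        raise ValueError("patient-grouped validation split requires >= 2 patients")

    # Pick a patient-grouped split whose training side contains every class
    # (mandatory: training is impossible otherwise, e.g. when weak labels
    # make patients label-pure and one class has a single patient).  Prefer
    # a split whose validation side also holds >= 2 classes; when no
    # candidate achieves that, early stopping monitors the training loss.
    n_present = len(np.unique(y))
    chosen = None
    val_informative = False
    for attempt in range(50):
        splitter = GroupShuffleSplit(
            n_splits=1,
            test_size=config.validation_fraction,
            random_state=(config.seed + attempt) % (2**32),
        )
        (train_idx, val_idx), = splitter.split(x, y, groups)
        if len(np.unique(y[train_idx])) < n_present:
            continue
        if len(np.unique(y[val_idx])) >= 2:
            chosen, val_informative = (train_idx, val_idx), True
            break
        if chosen is None:
            chosen = (train_idx, val_idx)
    if chosen is None:
        raise ValueError(
            "no patient-grouped split keeps all classes in the training set"
        )
    train_idx, val_idx = chosen
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    if config.class_balance:
        counts = np.bincount(y_tr, minlength=model.spec.n_classes).astype(float)
        class_w = np.where(counts > 0, len(y_tr) / (np.count_nonzero(counts) * counts), 0.0)
        w_tr, w_val = class_w[y_tr], class_w[y_val]
    else:
        w_tr = w_val = None

    rng = np.random.default_rng([config.seed, 1])
    opt = Adam(model.net.params, lr=config.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.net.get_state()
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = np.stack(
                [augment_tile(x_tr[i], config.augmentation_spec, rng) for i in idx]
            )
            wb = None if w_tr is None else w_tr[idx]
            loss, grads = model.net.loss_and_grads(xb, y_tr[idx], sample_weight=wb)
            opt.step(model.net.params, grads)
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / len(order))
        val_loss = model.net.loss(x_val, y_val, sample_weight=w_val)
        history.val_loss.append(val_loss)
        monitored = val_loss if val_informative else history.train_loss[-1]
        if monitored < best_val - 1e-12:
            best_val = monitored
            best_state = model.net.get_state()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                history.stopped_early = True
                break

    model.net.set_state(best_state)
    model.trained = True
    return model, history


def predict_tiles(model: TileClassifier, tiles) -> np.ndarray:
    """Per-tile class probabilities, order-aligned with the input.

    ``tiles`` may be Tile objects or raw RGB uint8 arrays.  Inference is
    deterministic (no augmentation, no dropout).
    """
    pixel_arrays = [t.pixels if isinstance(t, Tile) else t for t in tiles]
    x = prepare_tile_pixels(pixel_arrays, model.spec.input_size)
    return model.predict_proba(x)


def model_state(model: TileClassifier) -> dict:
    """Serializable snapshot: architecture, class order, and weights."""
    return {
        "spec": copy.deepcopy(model.spec),
        "class_order": model.class_order,
        "weights": model.net.get_state(),
        "trained": model.trained,
    }


def model_from_state(state: dict) -> TileClassifier:
    model = build_model(state["spec"], seed=0, class_order=tuple(state["class_order"]))
    model.net.set_state(state["weights"])
    model.trained = bool(state["trained"])
    return model
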