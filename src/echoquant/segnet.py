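"""Segmentation networks and their training/inference recipe.

Three U-net-family architectures (plain, residual-encoder, dense-encoder)
trained from scratch with pixel-wise cross-entropy, Adam (lr 1e-4), joint
flip/rotation augmentation, per-epoch seeded shuffling, and model selection
by best validation mean foreground Dice.  The full-scale training regime
(512 x 512 inputs, 200 epochs, batch 5) is the default configuration; a
desk-scale preset (64 px, 3 levels, 8 base channels, few epochs, larger
learning rate) is provided for CPU-sized experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from echoquant import schemes
from echoquant.nn import Adam, UNet, softmax_cross_entropy
from echoquant.schemes import as_view, class_codes

ARCHS = ("unet", "res_unet", "dense_unet")


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture and training hyperparameters for one view's model."""

    arch: str = "unet"
    view: str = "A2C"
    levels: int = 4
    base_channels: int = 16
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 5
    seed: int = 0
    augment: bool = True
    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    input_size: int = 512

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {ARCHS}")
        object.__setattr__(self, "view", as_view(self.view).value)
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.input_size % 2**self.levels:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^levels={2**self.levels}"
            )

    @property
    def n_classes(self) -> int:
        return len(class_codes(self.view))


def desk_config(view, arch: str = "unet", **overrides) -> SegModelConfig:
    """CPU-sized preset: 64 px inputs, 3 levels, 8 base channels, 8 epochs.

    The larger learning rate compensates for the short schedule.
    """
    base = dict(arch=arch, view=as_view(view).value, levels=3, base_channels=8,
                learning_rate=3e-3, epochs=8, batch_size=5, input_size=64)
    base.update(overrides)
    return SegModelConfig(**base)


@dataclass
class TrainedModel:
    """A network plus its config and training history."""

    net: UNet
    config: SegModelConfig
    history: list = field(default_factory=list)

    @property
    def codes(self):
        return np.asarray(class_codes(self.config.view), dtype=np.uint8)


def build_model(config: SegModelConfig) -> TrainedModel:
    """Instantiate an untrained network for ``config`` (He init, seeded)."""
    rng = np.random.default_rng(config.seed)
    net = UNet(config.arch, config.levels, config.base_channels, config.n_classes, rng=rng)
    return TrainedModel(net=net, config=config, history=[])


# ---------------------------------------------------------------------------
# augmentation


def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
            flip_prob: float = 0.5, rotation_deg: float = 15.0):
    """Jointly flip/rotate an image and its label map.

    Independent up-down and left-right flips with probability ``flip_prob``
    each, then a rotation by a uniform angle in +-``rotation_deg`` degrees
    (bilinear for the image, nearest-neighbour for the mask so labels stay
    integer).  ``flip_prob=0`` and ``rotation_deg=0`` give the identity.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    img, msk = image, mask
    if rng.random() < flip_prob:
        img, msk = img[::-1, :], msk[::-1, :]
    if rng.random() < flip_prob:
        img, msk = img[:, ::-1], msk[:, ::-1]
    angle = float(rng.uniform(-rotation_deg, rotation_deg)) if rotation_deg > 0 else 0.0
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant", cval=0)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# encoding / decoding between label codes and class channels


def encode_targets(masks: np.ndarray, view) -> np.ndarray:
    """Map view label codes to contiguous class indices (channel order)."""
    codes = class_codes(view)
    lut = np.zeros(256, dtype=np.int64)
    for i, c in enumerate(codes):
        lut[c] = i
    return lut[np.asarray(masks, dtype=np.uint8)]


def decode_logits(logits: np.ndarray, view) -> np.ndarray:
    """Per-pixel argmax over class scores, mapped back to view label codes.

    Ties break toward the lower class channel, i.e. the lower label code
    (background first).
    """
    codes = np.asarray(class_codes(view), dtype=np.uint8)
    return codes[np.argmax(logits, axis=0)]


def predict_mask(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Segment one preprocessed image; returns an integer label map."""
    s = model.config.input_size
    if image.shape != (s, s):
        raise ValueError(f"image shape {image.shape} does not match model input {s}x{s}")
    logits = model.net.forward(image[None, None].astype(np.float32), train=False)[0]
    return decode_logits(logits, model.config.view)


# ---------------------------------------------------------------------------
# training


def _mean_foreground_dice(model: TrainedModel, images: np.ndarray, masks: np.ndarray) -> float:
    from echoquant.agreement import dice

    codes = [c for c in class_codes(model.config.view) if c != schemes.BACKGROUND]
    scores = []
    for img, truth in zip(images, masks):
        pred = predict_mask(model, img)
        scores.extend(dice(pred, truth, c) for c in codes)
    return float(np.mean(scores)) if scores else 0.0


def train(model: TrainedModel, train_images, train_masks, val_images=None,
          val_masks=None, config: SegModelConfig | None = None) -> TrainedModel:
    """Train (in place) and return the model with best-validation weights.

    ``train_images``: (N, S, S) floats in [0, 1]; ``train_masks``: (N, S, S)
    view label codes.  The training set is reshuffled every epoch with a
    seeded generator; when a validation set is supplied the weights with the
    best validation mean foreground Dice are restored at the end.  History
    records (epoch, loss, val_dsc) per epoch.
    """
    config = config or model.config
    images = np.asarray(train_images, dtype=np.float32)
    masks = np.asarray(train_masks)
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    present = set(np.unique(masks).tolist())
    for code in class_codes(config.view):
        if code not in present:
            warnings.warn(
                f"label {code} absent from all training masks; training proceeds", stacklevel=2
            )

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.net.params(), lr=config.learning_rate)
    best_dsc, best_weights = -1.0, None
    n = images.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                pairs = [augment(images[i], masks[i], rng, config.flip_prob,
                                 config.rotation_deg) for i in idx]
                xb = np.stack([p[0] for p in pairs])[:, None]
                yb = encode_targets(np.stack([p[1] for p in pairs]), config.view)
            else:
                xb = images[idx][:, None]
                yb = encode_targets(masks[idx], config.view)
            logits = model.net.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_images is not None and len(val_images):
            val_dsc = _mean_foreground_dice(model, np.asarray(val_images, dtype=np.float32),
                                            np.asarray(val_masks))
            entry["val_dsc"] = val_dsc
            if val_dsc > best_dsc:
                best_dsc, best_weights = val_dsc, model.net.get_weights()
        model.history.append(entry)
    if best_weights is not None:
        model.net.set_weights(best_weights)
    return model


# ---------------------------------------------------------------------------
# ED / ES detection


class LVNotFoundError(ValueError):
    """No frame in the sequence contains the LV label."""


def detect_ed_es(masks) -> tuple[int, int]:
    """ED = frame of maximal LV-cavity area, ES = minimal; first index on ties."""
    areas = np.array([int((np.asarray(m) == schemes.LV).sum()) for m in masks])
    if areas.size < 2:
        raise ValueError("need at least 2 frames")
    if (areas == 0).all():
        raise LVNotFoundError("LV label absent from every frame")
    return int(np.argmax(areas)), int(np.argmin(areas))


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TrainedModel, path):
    """Save weights + config + history to a single .npz checkpoint."""
    import json

    from dataclasses import asdict

    weights = model.net.get_weights()
    np.savez_compressed(
        path,
        n_weights=len(weights),
        config=json.dumps(asdict(model.config)),
        history=json.dumps(model.history),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_model(path) -> TrainedModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        config = SegModelConfig(**json.loads(str(data["config"])))
        model = build_model(config)
        model.net.set_weights([data[f"w{i}"] for i in range(int(data["n_weights"]))])
        model.history = json.loads(str(data["history"]))
    return model
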