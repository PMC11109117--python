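"""Two-stage lesion segmentation and area extraction.

Stage 1 is a binary lesion/normal segmenter; stage 2 a seven-way subcategory
segmenter (codes 0-6). Both run on the full image; the stage-2 output is
gated by the stage-1 lesion mask, so every pixel the binary stage calls
normal is code 0 in the final map regardless of stage 2. Pixel areas per
subcategory are exact code counts of the final map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scoredfu.errors import ValidationError
from scoredfu.nn import Adam, UNet, softmax_cross_entropy, soft_dice_loss
from scoredfu.nn.models import normalize_batch
from scoredfu.types import LesionAreas, N_CODES, validate_labelmap


@dataclass(frozen=True)
class SegmenterConfig:
    """Architecture of one segmentation stage.

    ``classes`` is 2 for the binary stage or 7 for the subcategory stage.
    ``pretrained`` optionally names a checkpoint whose encoder weights
    warm-start this model (transfer from an earlier run); None trains from
    random initialization.
    """

    classes: int
    base_channels: int = 8
    depth: int = 2
    pretrained: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.classes not in (2, N_CODES):
            raise ValidationError(
                f"classes must be 2 (binary) or {N_CODES} (subcategories), "
                f"got {self.classes}"
            )
        if self.base_channels < 1 or self.depth < 1:
            raise ValidationError("base_channels and depth must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters shared by both stages."""

    epochs: int = 8
    learning_rate: float = 3e-3
    batch_size: int = 8
    loss: str = "ce"  # "ce" or "dice"
    val_fraction: float = 0.15
    lesion_pixels_only: bool = False  # stage-2 option: ignore background pixels

    def __post_init__(self):
        if self.loss not in ("ce", "dice"):
            raise ValidationError(f"loss must be 'ce' or 'dice', got {self.loss!r}")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")


def build_segmenter(config: SegmenterConfig) -> UNet:
    """Instantiate a U-Net per config; optionally warm-start the encoder."""
    model = UNet(classes=config.classes, base=config.base_channels,
                 depth=config.depth, seed=config.seed)
    if config.pretrained is not None:
        from scoredfu.io import load_checkpoint

        donor, _ = load_checkpoint(config.pretrained)
        if not isinstance(donor, UNet):
            raise ValidationError("pretrained checkpoint is not a segmenter")
        for dst, src in zip(model.encoder_params(), donor.encoder_params()):
            if dst.data.shape != src.data.shape:
                raise ValidationError(
                    "pretrained encoder shape mismatch; match base_channels/depth"
                )
            dst.data[...] = src.data
    return model


class OracleSegmenter:
    """A 'segmenter' that replays fixed ground-truth maps, keyed by image bytes.

    Used to inject known-perfect stages into the pipeline so downstream
    arithmetic can be checked in isolation.
    """

    def __init__(self, binary: bool = False):
        self.binary = binary
        self._maps: dict[bytes, np.ndarray] = {}

    def register(self, image: np.ndarray, labelmap: np.ndarray):
        lm = validate_labelmap(labelmap)
        self._maps[np.ascontiguousarray(image).tobytes()] = lm

    def predict_labelmap(self, image: np.ndarray) -> np.ndarray:
        lm = self._maps[np.ascontiguousarray(image).tobytes()]
        return (lm > 0).astype(np.uint8) if self.binary else lm


def _targets_for(model: UNet, labelmap: np.ndarray) -> np.ndarray:
    if model.classes == 2:
        return (labelmap > 0).astype(np.int64)
    return labelmap.astype(np.int64)


def binary_dice_on(model: UNet, dataset) -> float:
    """Mean lesion-vs-normal Dice of a model's predictions over a dataset."""
    from scoredfu.evaluation import dice

    vals = []
    for img, lm in dataset:
        pred = model.predict_labelmap(img) > 0
        vals.append(dice(pred, np.asarray(lm) > 0))
    return float(np.mean(vals))


def train_segmenter(
    model: UNet,
    dataset,
    hyperparams: TrainConfig | None = None,
    seed: int = 0,
    val_dataset=None,
):
    """Train a stage on (image, label-map) pairs; returns (model, history).

    History records per-epoch mean training loss and validation lesion Dice.
    With ``epochs=0`` the model is returned unchanged and the history is
    empty. Fully deterministic for a fixed seed.
    """
    hp = hyperparams or TrainConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValidationError("training dataset is empty")
    for img, lm in dataset:
        lm = validate_labelmap(lm)
        if img.shape[:2] != lm.shape:
            raise ValidationError("image / label-map dimension mismatch")

    rng = np.random.default_rng(seed)
    if val_dataset is None:
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(hp.val_fraction * len(dataset)))) if len(dataset) > 1 else 0
        val_dataset = [dataset[i] for i in idx[:n_val]]
        train_set = [dataset[i] for i in idx[n_val:]]
    else:
        train_set = dataset

    history = {"loss": [], "val_dice": []}
    if hp.epochs == 0:
        return model, history

    opt = Adam(model.params(), lr=hp.learning_rate)
    images = np.stack([img for img, _ in train_set])
    labels = np.stack([_targets_for(model, np.asarray(lm)) for _, lm in train_set])

    for _epoch in range(hp.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), hp.batch_size):
            sel = order[start:start + hp.batch_size]
            x = normalize_batch(images[sel])
            y = labels[sel]
            logits = model.forward(x)
            if hp.loss == "dice":
                loss, dlogits = soft_dice_loss(logits, y)
            else:
                loss, dlogits = softmax_cross_entropy(logits, y)
            if hp.lesion_pixels_only:
                mask = (y > 0)[:, None, :, :]
                n_lesion = max(int(mask.sum()), 1)
                dlogits = dlogits * mask * (y.size / n_lesion)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(
            binary_dice_on(model, val_dataset) if val_dataset else float("nan")
        )
    return model, history


def segment_two_stage(image: np.ndarray, binary_model, multiclass_model) -> np.ndarray:
    """Compose the cascade: stage-2 subcategory codes gated by the stage-1 mask."""
    image = np.asarray(image)
    mask = np.asarray(binary_model.predict_labelmap(image))
    if mask.shape != image.shape[:2]:
        raise ValidationError(
            f"stage-1 mask shape {mask.shape} != image {image.shape[:2]}"
        )
    codes = np.asarray(multiclass_model.predict_labelmap(image))
    if codes.shape != mask.shape:
        raise ValidationError(
            f"stage-2 map shape {codes.shape} != stage-1 mask {mask.shape}"
        )
    out = np.where(mask > 0, codes, 0).astype(np.uint8)
    return validate_labelmap(out)


def areas_from_labelmap(labelmap: np.ndarray) -> LesionAreas:
    """Exact per-code pixel counts of a label map."""
    lm = validate_labelmap(labelmap)
    counts = np.bincount(lm.reshape(-1), minlength=N_CODES)
    return LesionAreas(
        ulcer1=int(counts[1]),
        ulcer2=int(counts[2]),
        infection1=int(counts[3]),
        infection2=int(counts[4]),
        gangrene1=int(counts[5]),
        gangrene2=int(counts[6]),
    )
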