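"""Four-class severity stratification and class-activation explanation.

The classifier maps an RGB photograph to a probability vector over
(normal, infection, ulcer, gangrene) — "necrosis" is accepted as an alias of
gangrene on input. Saliency maps are gradient-weighted class-activation maps
computed at the last residual block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scoredfu.errors import ValidationError
from scoredfu.nn import Adam, ResNetTiny, softmax_cross_entropy
from scoredfu.nn.models import normalize_batch, normalize_image
from scoredfu.types import ClassProbabilities, Severity, SEVERITY_ORDER


@dataclass(frozen=True)
class ClassifierConfig:
    """Backbone size and initialization of the severity classifier.

    ``num_classes`` is fixed at 4. ``pretrained`` optionally names a
    checkpoint whose backbone (everything below the head) warm-starts this
    model; None trains from random initialization.
    """

    base_channels: int = 12
    pretrained: str | None = None
    num_classes: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.num_classes != 4:
            raise ValidationError(
                f"num_classes is fixed at 4, got {self.num_classes}"
            )
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")


@dataclass(frozen=True)
class ClassifierTrainConfig:
    """Training hyperparameters.

    The learning rate is multiplied by ``lr_decay`` once, at epoch
    ``lr_decay_at`` (default: two-thirds of the way through) — a single-step
    schedule that stabilizes the final epochs.
    """

    epochs: int = 15
    learning_rate: float = 1e-2
    batch_size: int = 16
    val_fraction: float = 0.15
    lr_decay: float = 0.3
    lr_decay_at: int | None = None

    def __post_init__(self):
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if not 0 < self.lr_decay <= 1:
            raise ValidationError("lr_decay must be in (0, 1]")

    @property
    def decay_epoch(self) -> int:
        return self.lr_decay_at if self.lr_decay_at is not None \
            else (2 * self.epochs) // 3


def build_classifier(config: ClassifierConfig) -> ResNetTiny:
    model = ResNetTiny(num_classes=config.num_classes, base=config.base_channels,
                       seed=config.seed)
    if config.pretrained is not None:
        from scoredfu.io import load_checkpoint

        donor, _ = load_checkpoint(config.pretrained)
        if not isinstance(donor, ResNetTiny):
            raise ValidationError("pretrained checkpoint is not a classifier")
        for dst, src in zip(model.backbone_params(), donor.backbone_params()):
            if dst.data.shape != src.data.shape:
                raise ValidationError("pretrained backbone shape mismatch")
            dst.data[...] = src.data
    return model


class OracleClassifier:
    """Replays fixed probability vectors keyed by image bytes (for testing
    downstream arithmetic with known-perfect stratification)."""

    def __init__(self):
        self._probs: dict[bytes, ClassProbabilities] = {}

    def register(self, image: np.ndarray, probs: ClassProbabilities):
        self._probs[np.ascontiguousarray(image).tobytes()] = probs

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        return self._probs[np.ascontiguousarray(image).tobytes()].as_vector()


def _label_index(label) -> int:
    if isinstance(label, Severity):
        return SEVERITY_ORDER.index(label)
    if isinstance(label, str):
        return SEVERITY_ORDER.index(Severity.from_name(label))
    idx = int(label)
    if not 0 <= idx < 4:
        raise ValidationError(f"label index {idx} outside the 4 classes")
    return idx


def accuracy_on(model, dataset) -> float:
    hits = [
        int(np.argmax(model.predict_proba(img))) == _label_index(lab)
        for img, lab in dataset
    ]
    return float(np.mean(hits))


def train_classifier(
    model: ResNetTiny,
    dataset,
    hyperparams: ClassifierTrainConfig | None = None,
    seed: int = 0,
    val_dataset=None,
):
    """Train on (image, severity label) pairs; returns (model, history).

    Labels may be Severity members, names (with the "necrosis" alias), or
    indices 0-3. History records per-epoch mean loss and validation accuracy.
    Deterministic for a fixed seed.
    """
    hp = hyperparams or ClassifierTrainConfig()
    dataset = [(img, _label_index(lab)) for img, lab in dataset]
    if not dataset:
        raise ValidationError("training dataset is empty")

    rng = np.random.default_rng(seed)
    if val_dataset is None:
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(hp.val_fraction * len(dataset)))) if len(dataset) > 1 else 0
        val_dataset = [dataset[i] for i in idx[:n_val]]
        train_set = [dataset[i] for i in idx[n_val:]]
    else:
        val_dataset = [(img, _label_index(lab)) for img, lab in val_dataset]
        train_set = dataset

    history = {"loss": [], "val_accuracy": []}
    if hp.epochs == 0:
        return model, history

    opt = Adam(model.params(), lr=hp.learning_rate)
    images = np.stack([img for img, _ in train_set])
    labels = np.array([lab for _, lab in train_set], dtype=np.int64)

    for _epoch in range(hp.epochs):
        if _epoch == hp.decay_epoch and hp.lr_decay < 1.0:
            opt.lr *= hp.lr_decay
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), hp.batch_size):
            sel = order[start:start + hp.batch_size]
            logits = model.forward(normalize_batch(images[sel]))
            loss, dlogits = softmax_cross_entropy(logits, labels[sel])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(
            accuracy_on(model, val_dataset) if val_dataset else float("nan")
        )
    return model, history


def classify(model, image: np.ndarray) -> ClassProbabilities:
    """Probability vector over the four severities for one image."""
    p = np.asarray(model.predict_proba(np.asarray(image)), dtype=float)
    return ClassProbabilities.from_vector(p)


def explain(model: ResNetTiny, image: np.ndarray, target_class) -> np.ndarray:
    """Gradient-weighted class-activation map for ``target_class``.

    Channel weights are the spatially averaged gradients of the target-class
    logit at the last residual block; the weighted activation sum is
    rectified, max-normalized to [0, 1] when non-degenerate, and upsampled
    (nearest) to the image dimensions.
    """
    image = np.asarray(image)
    tgt = _label_index(target_class)
    x = normalize_image(image)[None]
    logits = model.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, tgt] = 1.0
    model.backward(dlogits)

    acts = model.features[0]        # (C, h, w)
    grads = model.feature_grad[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()

    h, w = image.shape[:2]
    ry = h // cam.shape[0]
    rx = w // cam.shape[1]
    return cam.repeat(ry, axis=0).repeat(rx, axis=1).astype(np.float32)
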