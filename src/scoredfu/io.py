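"""File IO: PNG images and label maps, manifests, checkpoints, reports, configs.

Label maps are stored as single-channel 8-bit PNG with codes 0-6; the
round-trip is bit-exact. Checkpoints are ``.npz`` archives carrying the model
config (JSON) plus every parameter array.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from scoredfu.errors import ValidationError
from scoredfu.types import LesionAreas, ScoreBreakdown, ScoreWeights, validate_labelmap


# images and label maps -----------------------------------------------------

def save_image(path, image: np.ndarray):
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValidationError("expected an HxWx3 uint8 RGB image")
    Image.fromarray(image, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_labelmap(path, labelmap: np.ndarray):
    lm = validate_labelmap(labelmap)
    Image.fromarray(lm, mode="L").save(path)


def load_labelmap(path) -> np.ndarray:
    return validate_labelmap(np.asarray(Image.open(path).convert("L")))


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (height, width)."""
    h, w = size
    return np.asarray(Image.fromarray(image).resize((w, h), Image.BILINEAR))


def resize_labelmap(labelmap: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize — label codes must never be interpolated."""
    h, w = size
    lm = validate_labelmap(labelmap)
    return validate_labelmap(
        np.asarray(Image.fromarray(lm, mode="L").resize((w, h), Image.NEAREST))
    )


# manifests -----------------------------------------------------------------

MANIFEST_COLUMNS = [
    "filename", "severity_label",
    "ulcer1", "ulcer2", "infection1", "infection2", "gangrene1", "gangrene2",
]


def write_manifest(path, rows: list[dict]):
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return df


# checkpoints ---------------------------------------------------------------

def save_checkpoint(path, model, extra: dict | None = None):
    """Write model config + parameters (and optional metadata) as .npz."""
    meta = {"config": model.config(), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint; returns (model, extra metadata)."""
    from scoredfu.nn import ResNetTiny, UNet

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg = meta["config"]
    kind = cfg.pop("kind")
    if kind == "unet":
        model = UNet(**cfg)
    elif kind == "resnet_tiny":
        model = ResNetTiny(**cfg)
    else:
        raise ValidationError(f"unknown checkpoint kind {kind!r}")
    model.load_state_dict(state)
    return model, meta["extra"]


# score reports -------------------------------------------------------------

def weights_hash(weights: ScoreWeights) -> str:
    blob = json.dumps(weights.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def score_report(
    image_path,
    breakdown: ScoreBreakdown,
    areas: LesionAreas,
    probs,
    weights: ScoreWeights,
) -> dict:
    return {
        "image": str(image_path),
        "areas": areas.as_dict(),
        **breakdown.as_dict(),
        "p_normal": probs.normal,
        "p_infection": probs.infection,
        "p_ulcer": probs.ulcer,
        "p_gangrene": probs.gangrene,
        "predicted_severity": probs.argmax.value,
        "weights_hash": weights_hash(weights),
    }


def write_score_report(path, report: dict):
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# run configuration ---------------------------------------------------------

def load_config(path) -> dict:
    """YAML (or JSON — a YAML subset) run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg
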