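"""Desk-scale end-to-end experiments on synthetic scenes.

These routines run the full pipeline at a size a single CPU handles in
minutes: 64x64 scenes, encoder width 8, a few epochs. They exist so the
package's learning behaviour can be measured reproducibly — both the test
suite and the reproduction script call them.
"""

from __future__ import annotations

import numpy as np

from scoredfu.evaluation import agreement, stratified_split
from scoredfu.segmentation import (
    SegmenterConfig,
    TrainConfig,
    binary_dice_on,
    build_segmenter,
    segment_two_stage,
    train_segmenter,
)
from scoredfu.stratification import (
    ClassifierConfig,
    ClassifierTrainConfig,
    accuracy_on,
    build_classifier,
    explain,
    train_classifier,
)
from scoredfu.synth import generate_dataset
from scoredfu.types import Severity


def segmentation_recovery(seed: int, n_scenes: int = 200) -> dict:
    """Train both cascade stages on synthetic scenes; measure held-out quality.

    Returns held-out binary lesion Dice and two-stage per-pixel accuracy.
    """
    data = generate_dataset(n_scenes, (0.25, 0.25, 0.25, 0.25), seed=seed)
    labels = [t.severity_label for _, t in data]
    tr, va, te = stratified_split(labels, seed=seed + 1)
    train = [(data[i][0], data[i][1].label_map) for i in np.concatenate([tr, va])]
    test = [(data[i][0], data[i][1].label_map) for i in te]

    binary = build_segmenter(SegmenterConfig(classes=2, base_channels=8,
                                             seed=seed + 2))
    binary, _ = train_segmenter(binary, train, TrainConfig(), seed=seed + 3)
    multi = build_segmenter(SegmenterConfig(classes=7, base_channels=8,
                                            seed=seed + 4))
    multi, _ = train_segmenter(multi, train, TrainConfig(), seed=seed + 5)

    accs = [
        float((segment_two_stage(img, binary, multi) == np.asarray(lm)).mean())
        for img, lm in test
    ]
    return {
        "binary_dice": binary_dice_on(binary, test),
        "two_stage_pixel_accuracy": float(np.mean(accs)),
    }


def classification_recovery(seed: int, n_scenes: int = 400) -> dict:
    """Train the severity classifier; measure held-out accuracy and whether
    class-activation maps concentrate inside the lesion blobs."""
    data = generate_dataset(n_scenes, (0.25, 0.25, 0.25, 0.25), seed=seed)
    labels = [t.severity_label for _, t in data]
    tr, va, te = stratified_split(labels, seed=seed + 1)
    train = [(data[i][0], data[i][1].severity_label)
             for i in np.concatenate([tr, va])]
    test = [(data[i][0], data[i][1].severity_label) for i in te]

    model = build_classifier(ClassifierConfig(base_channels=8, seed=seed + 2))
    model, _ = train_classifier(model, train, ClassifierTrainConfig(),
                                seed=seed + 3)

    hits = total = 0
    for i in te:
        img, truth = data[i]
        if truth.severity_label == Severity.NORMAL:
            continue
        cam = explain(model, img, truth.severity_label)
        inside = np.asarray(truth.label_map) > 0
        if cam[inside].mean() > cam[~inside].mean():
            hits += 1
        total += 1
    return {
        "accuracy": accuracy_on(model, test),
        "gradcam_hit_rate": hits / total if total else float("nan"),
        "n_lesion_scenes": total,
    }


def agreement_recovery(seed: int, n: int = 20, bias: float = 1.5,
                       noise_sd: float = 0.5) -> dict:
    """Simulate a rater pair with a known systematic offset; recover it."""
    rng = np.random.default_rng(seed)
    reference = rng.uniform(20, 80, n)
    machine = reference + bias + rng.normal(0.0, noise_sd, n)
    rep = agreement(machine, reference)
    return {"bias": rep.bias, "loa_low": rep.loa_low, "loa_high": rep.loa_high,
            "p_value": rep.p_value, "stars": rep.stars}
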