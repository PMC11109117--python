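"""Severity scoring: area-share ratios, probability-weighted feature scores,
and the total score V.

For the three lesion families i in {ulcer, infection, gangrene} with level
areas S_i1, S_i2 (S_i = S_i1 + S_i2) and stratifier probability P_i:

    a_i = S_i / sum_i S_i                                (feature ratio)
    X_i = W_i * P_i * (W_i1*S_i1 + W_i2*S_i2) / sum_i S_i   (feature score)
    V   = C * sum_i X_i + epsilon                        (total score)

P_i is the raw softmax probability of the matching class (no renormalization
over the lesion classes; an optional flag renormalizes). With unit weights
and unit probabilities V collapses to C + epsilon for any positive areas,
which fixes the nominal scale. A lesion-free image (sum S_i = 0) is a valid
degenerate case: the ratio functions raise :class:`NoLesionError`, while the
total-score entry points return V = epsilon with the ``no_lesion`` flag set.
"""

from __future__ import annotations

import numpy as np

from scoredfu.errors import NoLesionError, ValidationError
from scoredfu.segmentation import areas_from_labelmap, segment_two_stage
from scoredfu.stratification import classify
from scoredfu.types import (
    ClassProbabilities,
    LesionAreas,
    ScoreBreakdown,
    ScoreWeights,
    Severity,
)

_FAMILIES = (Severity.ULCER, Severity.INFECTION, Severity.GANGRENE)


def feature_ratios(areas: LesionAreas) -> tuple[float, float, float]:
    """(a_ulcer, a_infection, a_gangrene) = family area shares; sums to 1.

    Raises :class:`NoLesionError` when the total lesional area is zero.
    """
    total = areas.total
    if total == 0:
        raise NoLesionError("no lesional pixels; feature ratios undefined")
    return (areas.ulcer / total, areas.infection / total, areas.gangrene / total)


def _lesion_probs(probs, renormalize: bool) -> dict[Severity, float]:
    """Per-family confidences from a ClassProbabilities or a plain mapping.

    A mapping with keys ulcer/infection/gangrene (values in [0, 1], no
    simplex constraint) supports direct formula evaluation, e.g. the
    unit-probability reduction where every P_i = 1.
    """
    if isinstance(probs, ClassProbabilities):
        p = {s: probs.for_severity(s) for s in _FAMILIES}
    else:
        d = {k.strip().lower(): float(v) for k, v in dict(probs).items()}
        if "necrosis" in d and "gangrene" not in d:
            d["gangrene"] = d.pop("necrosis")
        try:
            p = {s: d[s.value] for s in _FAMILIES}
        except KeyError as e:
            raise ValidationError(f"missing lesion probability {e}") from e
        for s, v in p.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"probability {s.value}={v} outside [0, 1]")
    if renormalize:
        z = sum(p.values())
        if z > 0:
            p = {s: v / z for s, v in p.items()}
    return p


def feature_scores(
    areas: LesionAreas,
    probs: "ClassProbabilities | dict",
    weights: ScoreWeights | None = None,
    renormalize_probs: bool = False,
) -> tuple[float, float, float]:
    """(X_ulcer, X_infection, X_gangrene) per the feature-score formula.

    Raises :class:`NoLesionError` when the total lesional area is zero.
    """
    weights = weights or ScoreWeights()
    total = areas.total
    if total == 0:
        raise NoLesionError("no lesional pixels; feature scores undefined")
    p = _lesion_probs(probs, renormalize_probs)
    out = []
    for fam, s1, s2 in (
        (Severity.ULCER, areas.ulcer1, areas.ulcer2),
        (Severity.INFECTION, areas.infection1, areas.infection2),
        (Severity.GANGRENE, areas.gangrene1, areas.gangrene2),
    ):
        w, w1, w2 = weights.family(fam)
        out.append(w * p[fam] * (w1 * s1 + w2 * s2) / total)
    return tuple(out)


def total_score(
    areas: LesionAreas,
    probs: "ClassProbabilities | dict",
    weights: ScoreWeights | None = None,
    renormalize_probs: bool = False,
    clamp: bool = False,
) -> ScoreBreakdown:
    """Full breakdown: ratios a_i, feature scores X_i and V = C*sum(X_i) + eps.

    A lesion-free image yields the degenerate breakdown (all a_i and X_i
    zero, V = epsilon, ``no_lesion=True``). With ``clamp=True`` V is clipped
    to [0, C]; scores are unclamped by default.
    """
    weights = weights or ScoreWeights()
    if areas.total == 0:
        v = weights.epsilon
        if clamp:
            v = float(np.clip(v, 0.0, weights.scale))
        return ScoreBreakdown(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, v=v, no_lesion=True)
    a_u, a_i, a_g = feature_ratios(areas)
    x_u, x_i, x_g = feature_scores(areas, probs, weights, renormalize_probs)
    v = weights.scale * (x_u + x_i + x_g) + weights.epsilon
    if clamp:
        v = float(np.clip(v, 0.0, weights.scale))
    return ScoreBreakdown(a_u, a_i, a_g, x_u, x_i, x_g, v=float(v))


def score_image(
    image: np.ndarray,
    binary_model,
    multiclass_model,
    classifier,
    weights: ScoreWeights | None = None,
    renormalize_probs: bool = False,
    clamp: bool = False,
):
    """Run the full pipeline on one image.

    Returns ``(breakdown, label_map, probabilities)`` where the breakdown is
    exactly ``total_score`` applied to the cascade's areas and the
    classifier's probabilities — full provenance for every score.
    """
    image = np.asarray(image)
    label_map = segment_two_stage(image, binary_model, multiclass_model)
    probs = classify(classifier, image)
    areas = areas_from_labelmap(label_map)
    breakdown = total_score(areas, probs, weights,
                            renormalize_probs=renormalize_probs, clamp=clamp)
    return breakdown, label_map, probs
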