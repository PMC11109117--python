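"""Evaluation: classification metrics, Dice/MIoU, ROC, splits, rater agreement.

Zero-denominator conventions: precision/recall/F1 with an empty denominator
return 0.0 (a warning is emitted); the Dice of two empty masks is 1.0;
mean-IoU skips classes absent from both maps. Multi-class summaries are
macro-averaged by default (micro and weighted also reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from scoredfu.errors import ValidationError
from scoredfu.types import ClassProbabilities, Severity, SEVERITY_ORDER


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary (one-vs-rest) confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be >= 0")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValidationError("all confusion counts are zero")


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, returning 0.0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from binary confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Row = true class, column = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValidationError(f"labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def per_class_counts(cm: np.ndarray, c: int) -> ConfusionCounts:
    """One-vs-rest reduction of a multi-class confusion matrix for class c."""
    tp = int(cm[c, c])
    fp = int(cm[:, c].sum() - tp)
    fn = int(cm[c, :].sum() - tp)
    tn = int(cm.sum() - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def multiclass_metrics(cm: np.ndarray) -> dict:
    """Per-class one-vs-rest metrics plus macro/micro/weighted averages."""
    k = cm.shape[0]
    total = cm.sum()
    per_class = {}
    support = cm.sum(axis=1)
    for c in range(k):
        counts = per_class_counts(cm, c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_class[c] = classification_metrics(counts)
    macro = {
        m: float(np.mean([per_class[c][m] for c in range(k)]))
        for m in ("precision", "recall", "f1")
    }
    weighted = {
        m: float(np.average([per_class[c][m] for c in range(k)],
                            weights=np.maximum(support, 1e-12)))
        for m in ("precision", "recall", "f1")
    }
    accuracy = float(np.trace(cm) / total) if total else 0.0
    micro = {"precision": accuracy, "recall": accuracy, "f1": accuracy}
    return {
        "accuracy": accuracy,
        "per_class": per_class,
        "macro": macro,
        "micro": micro,
        "weighted": weighted,
    }


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Binary overlap 2*TP / (FP + 2*TP + FN); both-empty masks give 1.0."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (fp + 2.0 * tp + fn)


def mean_iou(pred: np.ndarray, truth: np.ndarray, k: int = 6) -> float:
    """Mean over classes 0..k of per-class IoU = TP/(TP+FP+FN).

    Classes occurring in neither map are excluded from the mean (their IoU
    is the undefined 0/0).
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValidationError(f"map shapes differ: {pred.shape} vs {truth.shape}")
    if pred.size and max(pred.max(), truth.max()) > k:
        raise ValidationError(f"codes exceed k={k}")
    ious = []
    for c in range(k + 1):
        p = pred == c
        t = truth == c
        union = int(np.logical_or(p, t).sum())
        if union == 0:
            continue
        ious.append(int(np.logical_and(p, t).sum()) / union)
    if not ious:
        raise ValidationError("empty maps")
    return float(np.mean(ious))


def roc_analysis(probs, labels) -> dict:
    """One-vs-rest ROC curve and AUC per severity class.

    ``probs``: sequence of :class:`ClassProbabilities` (or (n, 4) array);
    ``labels``: severity names/members/indices. Classes without both a
    positive and a negative example are omitted. Raises on single-class input.
    """
    if isinstance(probs, np.ndarray):
        mat = probs
    else:
        mat = np.stack([
            p.as_vector() if isinstance(p, ClassProbabilities) else np.asarray(p)
            for p in probs
        ])
    y = np.array([_severity_index(lab) for lab in labels])
    if mat.shape[0] != y.shape[0]:
        raise ValidationError("probs and labels lengths differ")
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs at least two distinct labels")
    out = {}
    for c, sev in enumerate(SEVERITY_ORDER):
        pos = (y == c).astype(int)
        if pos.min() == pos.max():
            continue
        fpr, tpr, thr = _sk_roc_curve(pos, mat[:, c])
        out[sev.value] = {
            "fpr": fpr,
            "tpr": tpr,
            "thresholds": thr,
            "auc": float(_sk_auc(fpr, tpr)),
        }
    return out


def _severity_index(label) -> int:
    if isinstance(label, Severity):
        return SEVERITY_ORDER.index(label)
    if isinstance(label, str):
        return SEVERITY_ORDER.index(Severity.from_name(label))
    return int(label)


def stratified_split(labels, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Index triple (train, val, test); per-class shares follow ``ratios``.

    Within each class, counts are assigned by largest-remainder rounding
    (ties favouring the earlier split), so each class's split sizes are
    within one item of its exact shares. The three index arrays partition
    ``range(len(labels))`` and are reproducible under ``seed``.
    """
    ratios = np.asarray(ratios, dtype=float)
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ValidationError(f"ratios sum to {ratios.sum()}, expected 1")
    labels = np.asarray([_severity_index(l) if isinstance(l, (str, Severity)) else l
                         for l in labels])
    if labels.size == 0:
        raise ValidationError("empty dataset")
    rng = np.random.default_rng(seed)
    splits = [[], [], []]
    n_splits = len(ratios)
    global_exact = np.zeros(n_splits)
    global_assigned = np.zeros(n_splits, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValidationError(f"class {cls} has no items")
        idx = rng.permutation(idx)
        exact = idx.size * ratios
        global_exact += exact
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        # leftover items go to the largest remainder; exact ties are settled
        # by the split currently most under-allocated across classes, keeping
        # overall totals on the 7:2:1 marks as well
        for _ in range(idx.size - counts.sum()):
            deficit = global_exact - (global_assigned + counts)
            order = sorted(range(n_splits),
                           key=lambda s: (-rem[s], -deficit[s], s))
            pick = order[0]
            counts[pick] += 1
            rem[pick] = -1.0
        global_assigned += counts
        start = 0
        for s, cnt in enumerate(counts):
            splits[s].extend(idx[start:start + cnt].tolist())
            start += cnt
    return tuple(np.array(sorted(s), dtype=int) for s in splits)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman bias and limits of agreement plus paired-test significance."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    p_value: float
    stars: str
    n: int
    test: str


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def agreement(scores_machine, scores_reference, test: str = "wilcoxon") -> AgreementReport:
    """Bland-Altman agreement between paired machine and reference scores.

    bias = mean(machine - reference); limits of agreement = bias +/- 1.96*SD
    of the differences. Significance is a Wilcoxon signed-rank test by
    default (``test="ttest"`` selects a paired t-test); all-zero differences
    give p = 1 (no evidence of systematic difference).
    """
    m = np.asarray(scores_machine, dtype=float)
    r = np.asarray(scores_reference, dtype=float)
    if m.shape != r.shape:
        raise ValidationError(f"paired lists differ in length: {m.shape} vs {r.shape}")
    if m.ndim != 1 or m.size < 3:
        raise ValidationError("need paired 1-D lists of length >= 3")
    if test not in ("wilcoxon", "ttest"):
        raise ValidationError(f"unknown test {test!r}")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(d, 0.0):
        p = 1.0
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(m, r, zero_method="wilcox").pvalue)
    else:
        p = float(stats.ttest_rel(m, r).pvalue)
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        p_value=p,
        stars=significance_stars(p),
        n=int(m.size),
        test=test,
    )
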