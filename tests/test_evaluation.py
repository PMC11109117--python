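"""Metrics, ROC, splits and agreement against independent oracles."""

import numpy as np
import pytest

from scoredfu.errors import ValidationError
from scoredfu.evaluation import (
    AgreementReport,
    ConfusionCounts,
    agreement,
    classification_metrics,
    confusion_matrix,
    dice,
    mean_iou,
    multiclass_metrics,
    per_class_counts,
    roc_analysis,
    significance_stars,
    stratified_split,
)
from scoredfu.types import Severity


# --- classification metrics -------------------------------------------------

def test_binary_metrics_worked_example():
    m = classification_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
    assert m == pytest.approx(
        {"accuracy": 0.8, "precision": 0.75, "recall": 0.75, "f1": 0.75})


def test_perfect_prediction_gives_unit_metrics():
    m = classification_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
    assert m["precision"] == m["recall"] == m["f1"] == 1.0


def test_zero_denominator_returns_zero_with_warning():
    with pytest.warns(RuntimeWarning):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
    assert m["precision"] == 0.0


def brute_force_ovr(y_true, y_pred, c):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
    tn = len(y_true) - tp - fp - fn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def test_multiclass_metrics_match_brute_force_oracle(rng):
    y_true = rng.integers(0, 4, 200)
    y_pred = rng.integers(0, 4, 200)
    cm = confusion_matrix(y_true, y_pred, 4)
    out = multiclass_metrics(cm)
    assert out["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())
    for c in range(4):
        prec, rec, f1 = brute_force_ovr(y_true.tolist(), y_pred.tolist(), c)
        assert out["per_class"][c]["precision"] == pytest.approx(prec)
        assert out["per_class"][c]["recall"] == pytest.approx(rec)
        assert out["per_class"][c]["f1"] == pytest.approx(f1)
    macro_f1 = np.mean([brute_force_ovr(y_true.tolist(), y_pred.tolist(), c)[2]
                        for c in range(4)])
    assert out["macro"]["f1"] == pytest.approx(macro_f1)


def test_confusion_matrix_row_sums_equal_support(rng):
    y_true = rng.integers(0, 3, 60)
    y_pred = rng.integers(0, 3, 60)
    cm = confusion_matrix(y_true, y_pred, 3)
    for c in range(3):
        assert cm[c].sum() == (y_true == c).sum()
    counts = per_class_counts(cm, 0)
    assert counts.tp + counts.fp + counts.tn + counts.fn == 60


# --- dice / miou ------------------------------------------------------------

def test_dice_worked_examples():
    # TP=3, FP=1, FN=1 -> 2*3 / (1 + 6 + 1) = 0.75
    pred = np.array([1, 1, 1, 1, 0, 0])
    truth = np.array([1, 1, 1, 0, 1, 0])
    assert dice(pred, truth) == pytest.approx(0.75)
    assert dice(truth, truth) == 1.0
    assert dice(np.zeros(5), np.zeros(5)) == 1.0  # both-empty convention


def test_dice_equals_f1_on_random_masks(rng):
    for _ in range(50):
        pred = rng.integers(0, 2, (16, 16)).astype(bool)
        truth = rng.integers(0, 2, (16, 16)).astype(bool)
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        tn = 256 - tp - fp - fn
        if tp + fp + fn == 0:
            continue
        f1 = classification_metrics(ConfusionCounts(tp, fp, tn, fn))["f1"]
        assert dice(pred, truth) == pytest.approx(f1, abs=1e-12)


def brute_force_miou(pred, truth, k):
    vals = []
    for c in range(k + 1):
        inter = union = 0
        for p, t in zip(pred.reshape(-1), truth.reshape(-1)):
            if p == c or t == c:
                union += 1
                if p == c and t == c:
                    inter += 1
        if union:
            vals.append(inter / union)
    return sum(vals) / len(vals)


def test_miou_worked_examples(rng):
    lm = rng.integers(0, 7, (12, 12))
    assert mean_iou(lm, lm, k=6) == 1.0
    pred = np.zeros((2, 10), dtype=int)
    truth = np.concatenate([np.zeros((1, 10), int), np.ones((1, 10), int)])
    assert mean_iou(pred, truth, k=1) == pytest.approx(0.25)  # mean(0.5, 0)


def test_miou_matches_brute_force_oracle(rng):
    for _ in range(10):
        pred = rng.integers(0, 7, (9, 9))
        truth = rng.integers(0, 7, (9, 9))
        assert mean_iou(pred, truth, k=6) == pytest.approx(
            brute_force_miou(pred, truth, 6))


def test_mask_dim_mismatch_rejected():
    with pytest.raises(ValidationError):
        dice(np.zeros((3, 3)), np.zeros((4, 4)))
    with pytest.raises(ValidationError):
        mean_iou(np.zeros((3, 3), int), np.zeros((4, 4), int))


# --- ROC --------------------------------------------------------------------

def brute_force_auc(scores, positives):
    """Mann-Whitney pairwise-comparison identity."""
    pos = [s for s, y in zip(scores, positives) if y]
    neg = [s for s, y in zip(scores, positives) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation_gives_auc_one():
    probs = np.zeros((6, 4))
    probs[:3, 3] = 0.9
    probs[3:, 3] = 0.1
    probs[:, 0] = 1 - probs[:, 3]
    labels = ["gangrene"] * 3 + ["normal"] * 3
    out = roc_analysis(probs, labels)
    assert out["gangrene"]["auc"] == 1.0


def test_roc_auc_matches_pairwise_identity(rng):
    probs = rng.dirichlet(np.ones(4), size=24)
    labels = rng.integers(0, 4, 24)
    out = roc_analysis(probs, labels)
    for c, sev in enumerate(("normal", "infection", "ulcer", "gangrene")):
        if sev not in out:
            continue
        expected = brute_force_auc(probs[:, c].tolist(),
                                   (labels == c).tolist())
        assert out[sev]["auc"] == pytest.approx(expected)


def test_roc_permuted_labels_near_half(rng):
    n = 4000
    probs = rng.dirichlet(np.ones(4), size=n)
    labels = rng.integers(0, 4, n)  # independent of scores
    out = roc_analysis(probs, labels)
    for r in out.values():
        assert r["auc"] == pytest.approx(0.5, abs=0.05)


def test_roc_rejects_single_class():
    probs = np.tile([0.7, 0.1, 0.1, 0.1], (5, 1))
    with pytest.raises(ValidationError):
        roc_analysis(probs, ["normal"] * 5)


# --- stratified split -------------------------------------------------------

def test_split_exact_for_ten_per_class():
    labels = np.repeat(np.arange(4), 10)
    tr, va, te = stratified_split(labels, seed=3)
    for cls in range(4):
        assert (labels[tr] == cls).sum() == 7
        assert (labels[va] == cls).sum() == 2
        assert (labels[te] == cls).sum() == 1


def test_split_totals_and_partition():
    labels = np.repeat(np.arange(4), 25)
    tr, va, te = stratified_split(labels, seed=0)
    assert (len(tr), len(va), len(te)) == (70, 20, 10)
    allidx = np.concatenate([tr, va, te])
    assert sorted(allidx) == list(range(100))
    assert not (set(tr) & set(va)) and not (set(va) & set(te))


def test_split_clinical_style_class_sizes_within_one_item():
    sizes = {0: 543, 1: 440, 2: 489, 3: 472}
    labels = np.concatenate([np.full(n, c) for c, n in sizes.items()])
    tr, va, te = stratified_split(labels, ratios=(0.7, 0.2, 0.1), seed=8)
    for c, n in sizes.items():
        for part, ratio in ((tr, 0.7), (va, 0.2), (te, 0.1)):
            got = (labels[part] == c).sum()
            assert abs(got - n * ratio) <= 1
    assert len(tr) + len(va) + len(te) == sum(sizes.values())


def test_split_is_seed_reproducible_and_validates():
    labels = np.repeat(np.arange(2), 20)
    a = stratified_split(labels, seed=5)
    b = stratified_split(labels, seed=5)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)
    with pytest.raises(ValidationError):
        stratified_split(labels, ratios=(0.8, 0.1, 0.2))
    with pytest.raises(ValidationError):
        stratified_split([])
    # severity labels accepted too
    tr, va, te = stratified_split([Severity.NORMAL] * 5 + ["gangrene"] * 5)
    assert len(tr) + len(va) + len(te) == 10


# --- agreement --------------------------------------------------------------

def test_agreement_identical_lists():
    rep = agreement([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert rep.bias == 0.0
    assert rep.loa_low == rep.loa_high == 0.0
    assert rep.p_value == 1.0
    assert rep.stars == "ns"


def test_agreement_constant_offset():
    ref = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
    rep = agreement(ref + 2.0, ref)
    assert rep.bias == pytest.approx(2.0)
    assert rep.loa_low == pytest.approx(2.0)
    assert rep.loa_high == pytest.approx(2.0)


def test_agreement_recovers_simulated_bias():
    rng = np.random.default_rng(42)
    ref = rng.uniform(20, 80, 20)
    machine = ref + 1.5 + rng.normal(0, 0.5, 20)
    rep = agreement(machine, ref)
    assert rep.bias == pytest.approx(1.5, abs=0.4)
    assert rep.loa_low <= rep.bias <= rep.loa_high
    assert rep.stars == "***"  # consistent 1.5-point shift at n=20


def test_agreement_validates_input():
    with pytest.raises(ValidationError):
        agreement([1, 2, 3], [1, 2])
    with pytest.raises(ValidationError):
        agreement([1, 2], [1, 2])  # too short
    with pytest.raises(ValidationError):
        agreement([1, 2, 3], [1, 2, 3], test="anova")


def test_significance_star_bands():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.2) == "ns"


def test_agreement_ttest_flag():
    rng = np.random.default_rng(1)
    ref = rng.uniform(0, 10, 15)
    rep = agreement(ref + 1.0 + rng.normal(0, 0.2, 15), ref, test="ttest")
    assert isinstance(rep, AgreementReport)
    assert rep.test == "ttest"
    assert rep.p_value < 0.001


# --- figures ----------------------------------------------------------------

def test_plot_functions_write_files(tmp_path, rng):
    from scoredfu.plots import plot_bland_altman, plot_confusion, plot_roc

    probs = rng.dirichlet(np.ones(4), size=30)
    labels = rng.integers(0, 4, 30)
    plot_roc(roc_analysis(probs, labels), tmp_path / "roc.png")
    cm = confusion_matrix(labels, rng.integers(0, 4, 30), 4)
    plot_confusion(cm, tmp_path / "cm.png")
    ref = rng.uniform(0, 10, 12)
    machine = ref + 1.0
    rep = agreement(machine, ref)
    plot_bland_altman(machine, ref, rep, tmp_path / "ba.png")
    for name in ("roc.png", "cm.png", "ba.png"):
        assert (tmp_path / name).stat().st_size > 0
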