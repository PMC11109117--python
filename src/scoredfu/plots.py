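"""Evaluation figures: ROC curves, confusion heatmap, Bland-Altman plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from scoredfu.evaluation import AgreementReport
from scoredfu.types import SEVERITY_ORDER


def plot_roc(roc: dict, path):
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in roc.items():
        ax.plot(r["fpr"], r["tpr"], label=f"{name} (AUC={r['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_confusion(cm: np.ndarray, path, class_names=None):
    class_names = class_names or [s.value for s in SEVERITY_ORDER][: cm.shape[0]]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=9)
    ax.set_xticks(range(cm.shape[1]), class_names, rotation=45)
    ax.set_yticks(range(cm.shape[0]), class_names)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bland_altman(machine, reference, report: AgreementReport, path):
    m = np.asarray(machine, dtype=float)
    r = np.asarray(reference, dtype=float)
    mean = (m + r) / 2.0
    diff = m - r
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(mean, diff, s=14, alpha=0.7)
    for y, style in ((report.bias, "-"), (report.loa_low, "--"), (report.loa_high, "--")):
        ax.axhline(y, color="crimson", linestyle=style, lw=1)
    ax.set_xlabel("Mean of paired scores")
    ax.set_ylabel("Machine - reference")
    ax.set_title(f"bias={report.bias:.2f}  p={report.p_value:.3g} ({report.stars})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
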