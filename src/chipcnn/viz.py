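"""Plots for fit and cross-validation results."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ConfusionMatrix, MetricsReport


def plot_confusion(cm: ConfusionMatrix, path: str | Path | None = None,
                   title: str = "Confusion matrix"):
    """Heatmap of a (possibly fold-averaged) confusion matrix."""
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    im = ax.imshow(cm.counts, cmap="Blues")
    labels = [f"Level {i}" for i in range(4)]
    ax.set_xticks(range(4), labels, rotation=45, ha="right")
    ax.set_yticks(range(4), labels)
    ax.set_xlabel("Predicted level")
    ax.set_ylabel("Actual level")
    ax.set_title(title)
    for i in range(4):
        for j in range(4):
            v = cm.counts[i, j]
            ax.text(j, i, f"{v:g}", ha="center", va="center",
                    color="white" if v > cm.counts.max() / 2 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_roc(report: MetricsReport, path: str | Path | None = None):
    """One-vs-rest ROC curve per resistance level with AUC annotations."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for lv, pts in sorted(report.roc_points.items()):
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"Level {lv} (AUC {report.auc[lv]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate (1 - specificity)")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_history(history, path: str | Path | None = None):
    """Loss / accuracy / learning-rate curves of one training run."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    axes[0].plot(history["epoch"], history["loss"])
    axes[0].set_title("training loss")
    axes[1].plot(history["epoch"], history["accuracy"], label="train")
    if np.isfinite(history["val_accuracy"]).any():
        axes[1].plot(history["epoch"], history["val_accuracy"], label="val")
    axes[1].set_title("accuracy")
    axes[1].legend(fontsize=8)
    axes[2].semilogy(history["epoch"], history["learning_rate"])
    axes[2].set_title("learning rate")
    for ax in axes:
        ax.set_xlabel("epoch")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
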