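"""Optional figures: ROC curves, biomarker frequency bars, performance-class
pies and AUC boxplots. All functions take an axes (or create one) and
return it; nothing here affects the analysis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_roc(roc_points, auc=None, ax=None, label=None):
    """Plot one ROC curve (list of (FPR, TPR) points) with the chance line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr = [p[0] for p in roc_points]
    tpr = [p[1] for p in roc_points]
    text = label or "model"
    if auc is not None:
        text += f" (AUC {auc:.2f})"
    ax.plot(fpr, tpr, marker="o", ms=3, label=text)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("1 - specificity (FPR)")
    ax.set_ylabel("sensitivity (TPR)")
    ax.legend(frameon=False, fontsize=8)
    return ax

def plot_biomarker_counts(counts: dict, top_n: int = 20, ax=None):
    """Horizontal bars: how many evolved panels contain each taxon."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.25 * min(top_n, len(counts)) + 1))
    items = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[:top_n]
    names = [str(k) for k, _ in items][::-1]
    values = [v for _, v in items][::-1]
    ax.barh(names, values, color="#4c72b0")
    ax.set_xlabel("number of models containing taxon")
    return ax

def plot_performance_classes(class_counts: dict, ax=None, title=None):
    """Pie of poor/reasonable/good/excellent counts for one model family."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    order = ["poor", "reasonable", "good", "excellent"]
    values = [class_counts.get(c, 0) for c in order]
    keep = [(c, v) for c, v in zip(order, values) if v > 0]
    if keep:
        ax.pie(
            [v for _, v in keep],
            labels=[f"{c} ({v})" for c, v in keep],
            colors=["#c44e52", "#dd8452", "#55a868", "#4c72b0"][: len(keep)],
        )
    if title:
        ax.set_title(title)
    return ax

def plot_auc_box(auc_by_family: dict, ax=None):
    """Boxplot of AUC distributions, one box per model family."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    families = list(auc_by_family)
    ax.boxplot([auc_by_family[f] for f in families], tick_labels=families)
    ax.set_ylabel("ROC-AUC")
    return ax
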