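"""Figure helpers: clustered distance heatmap, CV boxplots, confusion
matrices, importance bars and dose-response panels.

All functions return the Matplotlib figure and optionally save it; they
are deliberately thin — everything scientific happens upstream.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import ClassifierReport


def _finish(fig, save_to: str | Path | None):
    fig.tight_layout()
    if save_to is not None:
        Path(save_to).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(save_to, dpi=150)
        plt.close(fig)
    return fig


def condition_distance_heatmap(
    distance: pd.DataFrame, leaf_order: list | None = None, save_to=None
):
    """Cosine-distance matrix between condition profiles, dendrogram order."""
    if leaf_order is not None:
        distance = distance.loc[leaf_order, leaf_order]
    labels = ["_".join(map(str, i)) if isinstance(i, tuple) else str(i)
              for i in distance.index]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(distance.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="cosine distance")
    ax.set_title("Phenotypic profile distances")
    return _finish(fig, save_to)


def cv_boxplot(reports: dict[str, ClassifierReport], save_to=None):
    """Spread of the 10-fold cross-validation accuracies per classifier."""
    fig, ax = plt.subplots(figsize=(5, 4))
    kinds = list(reports)
    ax.boxplot([reports[k].cv_scores for k in kinds], tick_labels=kinds)
    ax.set_ylabel("CV accuracy")
    ax.set_ylim(0, 1.05)
    ax.set_title("10-fold cross-validation")
    return _finish(fig, save_to)


def confusion_heatmap(report: ClassifierReport, save_to=None):
    c = report.confusion
    m = np.array([[c["TN"], c["FP"]], [c["FN"], c["TP"]]])
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(m, cmap="Blues")
    for (i, j), v in np.ndenumerate(m):
        ax.text(j, i, str(v), ha="center", va="center", fontsize=14)
    ax.set_xticks([0, 1], ["control", "treated"])
    ax.set_yticks([0, 1], ["control", "treated"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"{report.kind}: accuracy {report.test_accuracy:.2f}")
    return _finish(fig, save_to)


def importance_barplot(report: ClassifierReport, save_to=None):
    top = report.top10.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.barh(top["feature"], top["weight"], color="#31688e")
    ax.set_xlabel("normalized importance")
    ax.set_title(f"{report.kind}: top features")
    ax.tick_params(axis="y", labelsize=7)
    return _finish(fig, save_to)


def dose_response_panel(
    dose_response: pd.DataFrame, feature: str, save_to=None
):
    """Per-compound normalized means with 95% CI band and star tiers."""
    df = dose_response[dose_response["feature"] == feature]
    compounds = df["compound"].unique()
    fig, axes = plt.subplots(1, len(compounds), figsize=(3 * len(compounds), 3),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, comp in zip(axes, compounds):
        d = df[df["compound"] == comp].sort_values("dose_uM")
        x = np.arange(len(d))
        ax.fill_between(x, d["ci_low"], d["ci_high"], alpha=0.3, color="gray")
        ax.plot(x, d["normalized_mean"], "k-o", ms=4)
        for xi, (_, row) in zip(x, d.iterrows()):
            if row["stars"] not in ("", "ns"):
                ax.text(xi, row["ci_high"], row["stars"], ha="center", fontsize=10)
        ax.set_xticks(x, [f"{v:g}" for v in d["dose_uM"]])
        ax.set_xlabel("dose (uM)")
        ax.set_title(comp, fontsize=10)
    axes[0].set_ylabel(f"{feature}\n(fold of vehicle)")
    return _finish(fig, save_to)
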