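"""Plots: channel-wise correlation heatmaps, 2-D PCA of hidden features,
and hyperparameter-sweep curves.

Heatmap colours follow the red/white/green convention: strong negative
correlation red, near zero white, strong positive green, with bounds fixed
at [-1, 1] so plots from different subjects and emotions are comparable.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from sklearn.decomposition import PCA

from .features import ChannelWiseFeature

__all__ = ["plot_channel_wise", "plot_embedding", "plot_sweep", "CORR_CMAP"]

#: Diverging red-white-green map for correlations in [-1, 1].
CORR_CMAP = LinearSegmentedColormap.from_list(
    "corr_rwg", [(0.75, 0.1, 0.1), (1.0, 1.0, 1.0), (0.1, 0.55, 0.15)]
)


def plot_channel_wise(
    F: ChannelWiseFeature | np.ndarray,
    channel_names: Sequence[str] | None = None,
    ax: plt.Axes | None = None,
    title: str = "",
):
    """Heatmap of one C x C channel-wise correlation matrix."""
    m = F.matrix if isinstance(F, ChannelWiseFeature) else np.asarray(F)
    C = m.shape[0]
    if channel_names is not None and len(channel_names) != C:
        raise ValueError(
            f"{len(channel_names)} channel names for a {C}x{C} matrix"
        )
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, C / 6), max(3.5, C / 6)))
    im = ax.imshow(m, cmap=CORR_CMAP, vmin=-1.0, vmax=1.0, interpolation="nearest")
    if channel_names is not None:
        ax.set_xticks(range(C), channel_names, rotation=90, fontsize=6)
        ax.set_yticks(range(C), channel_names, fontsize=6)
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_embedding(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    class_names: Sequence[str] | None = None,
    ax: plt.Axes | None = None,
) -> tuple[plt.Axes, np.ndarray]:
    """2-component PCA scatter of hidden feature vectors, coloured by label.

    Returns the axes and the (n, 2) projected coordinates.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors")
    labels = np.asarray(labels)
    if np.allclose(X.var(axis=0), 0.0):
        warnings.warn("all feature vectors identical; embedding is degenerate")
        coords = np.zeros((X.shape[0], 2))
    else:
        coords = PCA(n_components=2).fit_transform(X)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(labels):
        sel = labels == cls
        name = class_names[cls] if class_names is not None else str(cls)
        ax.scatter(coords[sel, 0], coords[sel, 1], s=8, alpha=0.7, label=name)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.legend(fontsize=8)
    return ax, coords


def plot_sweep(table: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Accuracy vs each varied windowing parameter, one line per parameter."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for varied, grp in table[table["status"] == "ok"].groupby("varied"):
        ax.plot(grp[varied], grp["mean_accuracy"], marker="o", label=varied)
    ax.set_xlabel("parameter value")
    ax.set_ylabel("mean CV accuracy")
    ax.legend()
    return ax


def save_figure(ax: plt.Axes, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    return path
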