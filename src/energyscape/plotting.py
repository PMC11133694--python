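"""Basic plots: disconnectivity tree and group bar charts."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .landscape import DisconnectivityTree, TreeNode

__all__ = ["plot_disconnectivity_tree", "plot_group_bars"]


def plot_disconnectivity_tree(tree: DisconnectivityTree, ax: Optional[plt.Axes] = None):
    """Draw the disconnectivity tree: leaves at their minima energies,
    branches at their separation thresholds."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))

    x_next = [0.0]

    def layout(node: TreeNode) -> float:
        if node.is_leaf:
            x = x_next[0]
            x_next[0] += 1.0
            ax.plot([x, x], [node.energy, node.energy], "k")
            ax.annotate(f"min{node.minimum}", (x, node.energy),
                        textcoords="offset points", xytext=(0, -12), ha="center")
            return x
        xs = []
        for child in node.children:
            cx = layout(child)
            xs.append(cx)
            ax.plot([cx, cx], [child.energy, node.energy], "k")
        ax.plot([min(xs), max(xs)], [node.energy, node.energy], "k")
        return float(np.mean(xs))

    layout(tree.root)
    ax.set_ylabel("energy")
    ax.set_xticks([])
    return ax


def plot_group_bars(values_by_group: dict, labels, ylabel: str, ax=None):
    """Side-by-side bars of per-state (or per-pair) values for two groups."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    width = 0.8 / len(values_by_group)
    x = np.arange(len(labels))
    for i, (group, vals) in enumerate(values_by_group.items()):
        ax.bar(x + i * width, vals, width, label=str(group))
    ax.set_xticks(x + width / 2, labels)
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax
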