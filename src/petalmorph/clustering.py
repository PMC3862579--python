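"""Neighbor-joining dendrograms and heatmap ordering for trait matrices.

Cultivars are compared by Euclidean distance between rows of the
column-z-scored cultivar x parameter mean matrix (z-scoring stops cm^2
areas from dominating dimensionless shape factors); parameters are compared
between columns of the same matrix.  Trees come from the Saitou-Nei
neighbor-joining algorithm, which is exact on additive distances; ties in
the Q-criterion are broken deterministically toward the lexicographically
smallest label pair, and negative branch lengths are clamped to zero (and
counted).  Trees are returned as ``skbio.TreeNode`` and can be written as
Newick.  Heatmap rows/columns are ordered by a midpoint-rooted left-to-right
leaf traversal of the corresponding tree; values are rescaled per column to
[0, 1] and drawn red (low) to white (high).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

__all__ = [
    "DistanceMatrix",
    "cultivar_mean_matrix",
    "trait_distance_matrix",
    "neighbor_joining",
    "leaf_order",
    "heatmap_layout",
    "plot_heatmap",
]


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0):
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.values = 0.5 * (v + v.T)

    def __len__(self) -> int:
        return len(self.labels)


def cultivar_mean_matrix(t: pd.DataFrame, parameters: list[str] | None = None,
                         key: str = "genotype") -> pd.DataFrame:
    """Cultivar x parameter matrix of trait means from a long trait table.

    Missing cells are imputed by the column (parameter) mean; constant
    columns are dropped with a warning since they carry no distance signal
    after z-scoring.
    """
    import warnings

    wide = t.pivot_table(index=key, columns="trait", values="value",
                         aggfunc="mean")
    if parameters is not None:
        wide = wide[parameters]
    if wide.isna().any().any():
        warnings.warn("missing cultivar/parameter cells imputed by column mean",
                      stacklevel=2)
        wide = wide.fillna(wide.mean())
    const = wide.columns[wide.std(ddof=0) == 0]
    if len(const):
        warnings.warn(f"dropping constant parameters: {list(const)}", stacklevel=2)
        wide = wide.drop(columns=const)
    return wide


def trait_distance_matrix(matrix: pd.DataFrame, axis: str = "cultivars") -> DistanceMatrix:
    """Euclidean distances between rows (cultivars) or columns (parameters)
    of the column-z-scored mean matrix."""
    z = (matrix - matrix.mean()) / matrix.std(ddof=1)
    if axis == "cultivars":
        data, labels = z.to_numpy(), list(matrix.index)
    elif axis == "parameters":
        data, labels = z.to_numpy().T, list(matrix.columns)
    else:
        raise ValueError("axis must be 'cultivars' or 'parameters'")
    d = squareform(pdist(data, metric="euclidean"))
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree represented with a trifurcating root.  The
    joined pair at each step minimizes the Q-criterion; ties within 1e-12
    go to the lexicographically smallest pair of cluster labels (a cluster
    is labeled by its smallest leaf).  Negative branch lengths are clamped
    to 0; the number of clamps is stored as ``tree.negative_branches``.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(name=str(lbl)) for lbl in dm.labels]
    tags = [str(lbl) for lbl in dm.labels]  # smallest leaf label per cluster
    active = list(range(n))
    clamped = 0

    def set_length(node: TreeNode, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        node.length = float(length)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_tag = tuple(sorted((tags[i], tags[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair_tag < best[1]):
                    best = (q, pair_tag, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        # child order by cluster tag: leaf order independent of input order
        if tags[j] < tags[i]:
            parent.extend([nodes[j], nodes[i]])
        else:
            parent.extend([nodes[i], nodes[j]])
        # reduced distances to the new node, stored in slot i
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        tags[i] = min(tags[i], tags[j])
        active.remove(j)

    i, j, k = sorted(active, key=lambda a: tags[a])
    root = TreeNode()
    set_length(nodes[i], 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    set_length(nodes[j], 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    set_length(nodes[k], 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root.extend([nodes[i], nodes[j], nodes[k]])
    root.negative_branches = clamped
    return root


def leaf_order(tree: TreeNode) -> list[str]:
    """Deterministic display order: midpoint-rooted, left-to-right tips."""
    t = tree.copy()
    try:
        t = t.root_at_midpoint()
    except Exception:  # zero-length or degenerate trees keep their rooting
        pass
    return [tip.name for tip in t.tips()]


def heatmap_layout(
    matrix: pd.DataFrame,
    cultivar_tree: TreeNode,
    parameter_tree: TreeNode | None = None,
) -> pd.DataFrame:
    """Reorder the cultivar x parameter matrix by tree leaf order and rescale
    each column to [0, 1] (0 = red = lowest, 1 = white = highest)."""
    rows = leaf_order(cultivar_tree)
    if set(rows) != set(map(str, matrix.index)):
        raise ValueError("cultivar tree leaves do not match matrix rows")
    cols = list(map(str, matrix.columns))
    if parameter_tree is not None:
        cols = leaf_order(parameter_tree)
        if set(cols) != set(map(str, matrix.columns)):
            raise ValueError("parameter tree leaves do not match matrix columns")
    m = matrix.copy()
    m.index = m.index.map(str)
    m.columns = m.columns.map(str)
    m = m.loc[rows, cols]
    rng = m.max() - m.min()
    rng = rng.replace(0, 1.0)
    return (m - m.min()) / rng


def plot_heatmap(layout: pd.DataFrame, path: str | io.IOBase | None = None):
    """Draw the ordered heatmap with the red-to-white colormap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("red_white", ["red", "white"])
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * layout.shape[1]),
                                    max(4, 0.2 * layout.shape[0])))
    ax.pcolormesh(layout.to_numpy(), cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(np.arange(layout.shape[1]) + 0.5, layout.columns,
                  rotation=90, fontsize=6)
    ax.set_yticks(np.arange(layout.shape[0]) + 0.5, layout.index, fontsize=6)
    ax.invert_yaxis()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
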