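"""Hierarchical clustering of per-bag RQ profiles across storage days.

A profile matrix holds one target miRNA's relative quantities with bags
as rows and storage days as columns.  Bags (or, transposed, days) are
clustered on plain Euclidean distance; the default linkage is average
(UPGMA).  The module exposes the distance matrix, the merge sequence
and leaf order, and an optional heatmap export in the conventional
blue-low / red-high colouring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "profile_matrix",
    "distance_matrix",
    "hierarchical_cluster",
    "ClusterResult",
    "save_heatmap",
]

LINKAGES = ("average", "single", "complete", "ward")


def profile_matrix(rq_results: pd.DataFrame, target: str) -> pd.DataFrame:
    """Pivot per-bag RQ results into a bags x days matrix for one target.

    Missing cells are not imputed; they surface as NaN and are rejected
    by :func:`distance_matrix`, which directs the caller to drop or fill
    the affected bags explicitly.
    """
    sub = rq_results[rq_results["target"] == target]
    if sub.empty:
        raise ValueError(f"no RQ results for target {target!r}")
    wide = sub.pivot_table(index="bag_id", columns="day", values="rq", aggfunc="first")
    wide = wide.sort_index()
    wide.columns = [int(c) for c in wide.columns]
    return wide


def distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between profile rows.

    Symmetric with a zero diagonal.  NaN cells are an error: apply an
    imputation or row-drop policy before clustering.
    """
    if len(profiles.index) < 2:
        raise ValueError("need at least 2 rows to compute distances")
    values = profiles.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = profiles.index[np.isnan(values).any(axis=1)].tolist()
        raise ValueError(
            f"NaN cells in rows {bad}; impute or drop incomplete profiles first"
        )
    dist = squareform(pdist(values, metric="euclidean"))
    return pd.DataFrame(dist, index=profiles.index, columns=profiles.index)


class ClusterResult:
    """Dendrogram of one hierarchical clustering run.

    ``merges`` is the SciPy linkage matrix (each row: the two merged
    cluster indices, the merge height, and the new cluster size);
    ``leaf_order`` lists the input labels in dendrogram order.
    """

    def __init__(self, labels: list, merges: np.ndarray):
        self.labels = list(labels)
        self.merges = merges
        if len(merges):
            self.leaf_order = [self.labels[i] for i in hierarchy.leaves_list(merges)]
        else:
            self.leaf_order = list(self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# leaf_order\t" + "\t".join(map(str, self.leaf_order)) + "\n")
            pd.DataFrame(
                self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
            ).to_csv(fh, sep="\t", index=False)


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "average") -> ClusterResult:
    """Cluster a precomputed distance matrix.

    The merge sequence is deterministic: SciPy resolves equal-height
    candidates by lowest cluster index.  Merge heights are
    non-decreasing for the monotone linkages exposed here.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    values = dist.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(dist.index) == 1:
        return ClusterResult(list(dist.index), np.empty((0, 4)))
    condensed = squareform(values, checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult(list(dist.index), merges)


def save_heatmap(profiles: pd.DataFrame, path, *, title: str = "", z_score_rows: bool = False) -> None:
    """Write a blue-low/red-high heatmap PNG of a profile matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = profiles.to_numpy(dtype=float)
    if z_score_rows:
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    fig, ax = plt.subplots(figsize=(6, max(3, 0.06 * len(profiles))))
    im = ax.imshow(data, aspect="auto", cmap="bwr")
    ax.set_xticks(range(len(profiles.columns)), [f"day {c}" for c in profiles.columns])
    ax.set_ylabel("PC bag")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="RQ (z-scored)" if z_score_rows else "RQ")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
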