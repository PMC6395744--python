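"""Unsupervised hierarchical clustering of muscles and genes with heatmap export.

Agglomerative clustering on the standardized expression matrix — the same
matrix PCA consumes — sorts both muscles (rows) and genes (columns) by their
dendrograms and cuts the trees into k clusters, reproducing the two-cluster
segregation of the ubiquitous-SOD1 muscles from everything else.  The
reordered CSV is the authoritative export; the rendered heatmap image is a
convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "Dendrogram",
    "ClusterCut",
    "agglomerative_linkage",
    "cut_clusters",
    "export_heatmap",
]

_METRICS = {"euclidean", "correlation"}
_LINKAGES = {"average", "complete", "ward"}


@dataclass
class Dendrogram:
    """Merge table (scipy linkage format) plus the ordered leaves.

    ``merges`` has n-1 rows of (child id, child id, merge height, new size);
    ``leaf_order`` is the left-to-right dendrogram ordering of the original
    item indices; ``labels`` carries the item names along that axis.
    """

    merges: np.ndarray
    leaf_order: np.ndarray
    labels: list[str]
    axis: str
    metric: str
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


@dataclass
class ClusterCut:
    k: int
    labels: np.ndarray  # cluster id per original item index


def agglomerative_linkage(
    z: pd.DataFrame,
    axis: str = "rows",
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Standard agglomerative merge sequence along the chosen axis.

    Column (gene) clustering simply transposes the matrix first.  Ward
    linkage requires the euclidean metric.
    """
    if axis not in {"rows", "columns"}:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}, got {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")

    data = z if axis == "rows" else z.T
    if data.isna().any().any():
        raise ValueError("clustering input contains NaN")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")

    dists = pdist(data.to_numpy(dtype=float), metric=metric)
    merges = hierarchy.linkage(dists, method=linkage)
    leaf_order = np.asarray(hierarchy.leaves_list(merges))
    return Dendrogram(
        merges=merges,
        leaf_order=leaf_order,
        labels=list(data.index),
        axis=axis,
        metric=metric,
        linkage=linkage,
    )


def cut_clusters(d: Dendrogram, k: int) -> ClusterCut:
    """Cut the tree into exactly k clusters by undoing the k-1 highest merges."""
    if not 1 <= k <= d.n_leaves:
        raise ValueError(f"k must be in [1, {d.n_leaves}], got {k}")
    labels = hierarchy.cut_tree(d.merges, n_clusters=k).ravel()
    return ClusterCut(k=k, labels=labels)


def export_heatmap(
    z: pd.DataFrame,
    row_dendrogram: Dendrogram,
    col_dendrogram: Dendrogram,
    path: str,
    image: bool = True,
    header_lines: list[str] | None = None,
) -> dict[str, str]:
    """Write the dendrogram-reordered standardized matrix.

    ``path`` is the CSV destination (cell values equal ``z`` exactly); a PNG
    with the same stem is rendered alongside unless ``image`` is False.
    Returns the written paths.
    """
    if row_dendrogram.n_leaves != z.shape[0] or col_dendrogram.n_leaves != z.shape[1]:
        raise ValueError("dendrogram sizes do not match matrix dimensions")
    ordered = z.iloc[row_dendrogram.leaf_order, col_dendrogram.leaf_order]

    paths = {"csv": str(path)}
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            ordered.to_csv(fh, index_label="sample_id")
    except OSError as err:
        raise OSError(f"failed to write heatmap CSV to {path}: {err}") from err

    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        png = str(path)
        png = png[:-4] + ".png" if png.endswith(".csv") else png + ".png"
        fig, ax = plt.subplots(figsize=(10, 7))
        sns.heatmap(
            ordered, cmap="vlag", center=0.0, ax=ax,
            cbar_kws={"label": "standardized expression"},
        )
        ax.set_xlabel("gene")
        ax.set_ylabel("muscle")
        fig.tight_layout()
        try:
            fig.savefig(png, dpi=150, metadata={"Software": "myodisc"})
        except OSError as err:
            raise OSError(f"failed to write heatmap image to {png}: {err}") from err
        finally:
            plt.close(fig)
        paths["png"] = png
    return paths
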