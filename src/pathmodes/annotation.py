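"""Cluster-free cell-type annotation from marker gene lists.

Each marker list is scored with the *first* activation mode only (PC1 of
the marker submatrix, oriented and 0-1 scaled); the list's row enters the
annotation activity matrix only if that mode passes the informativity gate,
so uninformative marker lists are silently excluded from labeling.  Cells
are then clustered on the activity matrix — k-nearest-neighbor graph with
Jaccard-similarity edge weights, Leiden communities under modularity — and
each cluster receives the cell type with the highest mean activity, or
``"unassigned"`` when no mean activity exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .gene_sets import GeneSetCollection
from .informativity import ModeParams
from .metrics import UNASSIGNED
from .modes import ActivationMode, ActivityMatrix, detect_pathway_modes


@dataclass(frozen=True)
class AnnotationParams:
    """Graph-clustering and label-assignment parameters."""

    k_neighbors: int = 20
    assign_threshold: float = 0.0
    leiden_max_iter: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if self.leiden_max_iter < 1:
            raise ValueError("leiden_max_iter must be >= 1")


@dataclass
class AnnotationResult:
    """Per-cell cluster ids and predicted labels, plus the cluster means."""

    cell_ids: list[str]
    cluster: np.ndarray  # per-cell community id
    label: list[str]  # per-cell cell type or "unassigned"
    cluster_scores: pd.DataFrame  # clusters x cell types, mean activity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "cluster": self.cluster, "label": self.label}
        )


def first_mode_activity(
    m, markers: GeneSetCollection, mode_params: ModeParams | None = None
) -> ActivityMatrix:
    """Score every marker list with its first activation mode.

    Rows are named after the marker sets (cell types).  Lists absent from
    the matrix or whose first mode fails the informativity gate are dropped
    with a warning; an error is raised only if nothing survives.
    """
    mode_params = (mode_params or ModeParams()).with_(max_modes=1)
    rows: list[np.ndarray] = []
    names: list[str] = []
    kept: list[ActivationMode] = []
    for marker_set in markers:
        result = detect_pathway_modes(m, marker_set, mode_params)
        if result.informative:
            mode = result.informative[0]
            rows.append(mode.scores)
            names.append(marker_set.name)
            kept.append(mode)
        else:
            warnings.warn(
                f"marker list {marker_set.name!r}: first mode not informative; "
                "cell type excluded from annotation",
                stacklevel=2,
            )
    if not rows:
        raise ValueError(
            "no marker list yielded an informative first mode; review the "
            "marker lists (gene symbols, list sizes) against the dataset"
        )
    return ActivityMatrix(
        values=np.vstack(rows),
        mode_names=names,
        cell_ids=list(m.cell_ids),
        modes=kept,
    )


def _jaccard_knn_graph(points: np.ndarray, k: int) -> ig.Graph:
    """Weighted graph with Jaccard similarity of (k+1)-neighbor sets.

    Neighbor sets include the cell itself, which stabilizes the similarity
    for small k.  Zero-similarity pairs contribute no edge.
    """
    n = points.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    ind = nn.kneighbors(points, return_distance=False)
    neighbor_sets = np.empty((n, k + 1), dtype=np.int64)
    for i in range(n):
        row = ind[i]
        if i in row:
            neighbor_sets[i] = row
        else:  # exact duplicates can crowd the query point out of its own list
            neighbor_sets[i] = np.concatenate(([i], row[: k]))
    size = k + 1
    data = np.ones(neighbor_sets.size)
    indptr = np.arange(0, neighbor_sets.size + 1, size)
    b = sparse.csr_matrix(
        (data, neighbor_sets.ravel(), indptr), shape=(n, n)
    )
    inter = (b @ b.T).tocoo()
    jac = inter.data / (2.0 * size - inter.data)
    mask = (inter.row < inter.col) & (jac > 0)
    edges = list(zip(inter.row[mask].tolist(), inter.col[mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[mask].tolist()
    return g


def cluster_activity(
    activity: ActivityMatrix | np.ndarray,
    params: AnnotationParams | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Leiden communities of cells in activity space.

    Cells are points whose coordinates are the activity-matrix columns
    (any features x cells matrix is accepted, e.g. a gene-space matrix for
    comparison runs).  Deterministic given the seed.
    """
    params = params or AnnotationParams()
    if seed is None:
        seed = params.seed
    values = (
        activity.values if isinstance(activity, ActivityMatrix) else np.asarray(activity)
    )
    n_cells = values.shape[1]
    if n_cells <= params.k_neighbors:
        raise ValueError(
            f"need more cells ({n_cells}) than k_neighbors ({params.k_neighbors})"
        )
    if np.all(values == values[:, :1]):
        return np.zeros(n_cells, dtype=int)  # degenerate: all cells identical
    graph = _jaccard_knn_graph(np.ascontiguousarray(values.T, dtype=float), params.k_neighbors)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.ModularityVertexPartition,
        weights="weight",
        n_iterations=params.leiden_max_iter,
        seed=int(seed),
    )
    return np.asarray(partition.membership, dtype=int)


def label_clusters(
    activity: ActivityMatrix,
    clusters: np.ndarray,
    params: AnnotationParams | None = None,
) -> AnnotationResult:
    """Assign each cluster the cell type with the highest mean activity.

    The winner must *strictly* exceed ``assign_threshold`` (with 0-1 scaled
    scores the default threshold 0 accepts any positive mean activity);
    otherwise the cluster is labeled ``"unassigned"``.  Ties are broken by
    cell-type name order, with a warning.
    """
    params = params or AnnotationParams()
    clusters = np.asarray(clusters)
    if clusters.shape[0] != activity.n_cells:
        raise ValueError("clusters must cover every cell of the activity matrix")
    frame = activity.to_frame()
    cluster_scores = frame.T.groupby(clusters).mean()  # clusters x cell types
    labels_by_cluster: dict = {}
    for cluster_id, row in cluster_scores.iterrows():
        best = row.max()
        if best > params.assign_threshold:
            winners = sorted(row.index[row == best])
            if len(winners) > 1:
                warnings.warn(
                    f"cluster {cluster_id}: tie between {winners}; "
                    "picking first by name order",
                    stacklevel=2,
                )
            labels_by_cluster[cluster_id] = winners[0]
        else:
            labels_by_cluster[cluster_id] = UNASSIGNED
    label = [labels_by_cluster[c] for c in clusters]
    return AnnotationResult(
        cell_ids=list(activity.cell_ids),
        cluster=clusters,
        label=label,
        cluster_scores=cluster_scores,
    )


def annotate(
    m,
    markers: GeneSetCollection,
    mode_params: ModeParams | None = None,
    params: AnnotationParams | None = None,
) -> AnnotationResult:
    """End-to-end annotation: score markers, cluster, label clusters."""
    params = params or AnnotationParams()
    activity = first_mode_activity(m, markers, mode_params)
    clusters = cluster_activity(activity, params)
    return label_clusters(activity, clusters, params)
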