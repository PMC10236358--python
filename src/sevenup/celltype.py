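"""Cell types: reference clustering, kNN label transfer, substitution typing.

Ground truth is produced the way CODEX studies do it: PCA of the
normalized full-panel expression matrix (top 20 PCs), a k-nearest-neighbor
graph (k = 30, Euclidean, union-symmetrized), modularity community
detection (Leiden), manual (here: programmatic) annotation of clusters to
cell-type names, all on a reference subset of up to 10,000 cells; a
majority-vote kNN classifier anchored on that labeled reference then
transfers labels to everything else.

To type cells whose panel is partly imputed, the measured subset of
expressions is kept and the imputed values are *substituted* for the
markers that were not measured; the assembled full-width vector goes
through the same stored PCA basis and the same kNN reference.  Feeding the
true measured values through this substitution path therefore reproduces
the ground-truth labels exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from sevenup.exceptions import AnnotationError, DimensionMismatchError, SevenUpError
from sevenup.io_formats import NORM_PREFIX, CellTable

logger = logging.getLogger(__name__)

N_PCS = 20
KNN_GRAPH_K = 30
REFERENCE_SIZE = 10_000
K_CLASSIFY = 30  # transfer k; kept equal to the graph k


def _pca_fit(x: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Centering vector and top-n_pcs loadings (rows are components)."""
    mean = x.mean(axis=0)
    xc = x - mean
    # deterministic full SVD with sign convention fixed by the loadings
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    vt = vt[:n_pcs]
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return mean, vt * signs[:, None]


def knn_graph_edges(coords: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrized kNN edge list (unordered pairs, deduplicated)."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(coords)))
    nn.fit(coords)
    _, idx = nn.kneighbors(coords)
    src = np.repeat(np.arange(len(coords)), idx.shape[1] - 1)
    dst = idx[:, 1:].ravel()  # drop self
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    return np.unique(np.stack([lo, hi], axis=1), axis=0)


def cluster_reference(
    table: CellTable,
    markers: list[str] | None = None,
    n_pcs: int = N_PCS,
    k: int = KNN_GRAPH_K,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells on top-``n_pcs`` PCs via a kNN graph + Leiden; stable
    under a fixed seed."""
    markers = list(markers) if markers is not None else list(table.normalized_markers)
    x = table.norm_matrix(markers)
    if len(x) <= k:
        raise SevenUpError(f"need more than k={k} cells to build the graph")
    mean, components = _pca_fit(x, min(n_pcs, x.shape[1]))
    coords = (x - mean) @ components.T
    edges = knn_graph_edges(coords, k)
    graph = igraph.Graph(n=len(x), edges=[tuple(e) for e in edges])
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(partition.membership, dtype=np.int64)


def annotate_clusters_by_majority(
    cluster_ids: np.ndarray, true_types: np.ndarray
) -> dict[int, str]:
    """Cluster → type-name map by majority vote of known per-cell types.

    Stands in for the manual expert annotation step when ground truth is
    available (synthetic data, benchmarks).
    """
    df = pd.DataFrame({"cluster": cluster_ids, "type": true_types})
    return {
        int(c): str(grp["type"].mode().iloc[0]) for c, grp in df.groupby("cluster")
    }


@dataclass
class TypingModel:
    """Stored PCA basis + labeled kNN reference in PC space."""

    markers: tuple[str, ...]  # full panel, fixed order
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (n_pcs, n_markers)
    reference_coords: np.ndarray  # (n_ref, n_pcs)
    reference_labels: np.ndarray  # int codes into class_names
    class_names: tuple[str, ...]  # ordered by reference frequency (desc)
    k_classify: int = K_CLASSIFY

    def project(self, x_full: np.ndarray) -> np.ndarray:
        if x_full.shape[1] != len(self.markers):
            raise DimensionMismatchError(
                f"expected {len(self.markers)} markers, got {x_full.shape[1]}"
            )
        return (x_full - self.pca_mean) @ self.pca_components.T

    def classify(self, coords: np.ndarray) -> np.ndarray:
        """Majority vote among the k nearest reference cells; ties break
        toward the class more frequent in the reference."""
        if len(coords) == 0:
            return np.array([], dtype=object)
        nn = NearestNeighbors(n_neighbors=min(self.k_classify, len(self.reference_coords)))
        nn.fit(self.reference_coords)
        _, idx = nn.kneighbors(coords)
        votes = self.reference_labels[idx]  # (n, k)
        n_classes = len(self.class_names)
        counts = np.zeros((len(coords), n_classes), dtype=np.int64)
        for c in range(n_classes):
            counts[:, c] = (votes == c).sum(axis=1)
        # class codes are frequency-ranked, so argmax's first-wins tie-break
        # lands on the more frequent class
        winners = counts.argmax(axis=1)
        return np.array([self.class_names[w] for w in winners], dtype=object)


def fit_typing_model(
    table: CellTable,
    cluster_ids: np.ndarray,
    cluster_annotation: dict[int, str],
    markers: list[str] | None = None,
    n_ref: int = REFERENCE_SIZE,
    k_classify: int = K_CLASSIFY,
    n_pcs: int = N_PCS,
    seed: int = 0,
) -> TypingModel:
    """Build the label-transfer model from annotated clusters.

    A uniform random subsample of min(n_ref, n_cells) labeled cells is
    stored in PC space; the PCA basis is fit on that reference subset and
    applied unchanged at prediction.
    """
    markers = tuple(markers) if markers is not None else tuple(table.normalized_markers)
    unknown = sorted(set(np.unique(cluster_ids).tolist()) - set(cluster_annotation))
    if unknown:
        raise AnnotationError(f"clusters without annotation: {unknown}")
    labels = np.array([cluster_annotation[int(c)] for c in cluster_ids], dtype=object)
    rng = np.random.default_rng(seed)
    n = len(table)
    take = rng.permutation(n)[: min(n_ref, n)]
    x = table.norm_matrix(markers)[take]
    y = labels[take]
    freq = pd.Series(y).value_counts()  # desc frequency → class order
    class_names = tuple(str(c) for c in freq.index)
    code = {c: i for i, c in enumerate(class_names)}
    mean, components = _pca_fit(x, min(n_pcs, x.shape[1]))
    return TypingModel(
        markers=markers,
        pca_mean=mean,
        pca_components=components,
        reference_coords=(x - mean) @ components.T,
        reference_labels=np.array([code[str(v)] for v in y], dtype=np.int64),
        class_names=class_names,
        k_classify=k_classify,
    )


def predict_types(model: TypingModel, table: CellTable) -> np.ndarray:
    """Type cells whose table already holds normalized values for the full
    panel (ground-truth path)."""
    return model.classify(model.project(table.norm_matrix(model.markers)))


def predict_types_with_substitution(
    model: TypingModel,
    measured_table: CellTable,
    measured_markers: list[str],
    imputed_table: CellTable,
) -> np.ndarray:
    """Type cells from measured + imputed values.

    Assembles the full-width expression vector — measured values at the
    measured panel's indices, imputed values elsewhere — projects it with
    the stored PCA basis, and classifies against the same kNN reference.
    """
    measured_set = set(measured_markers)
    missing = measured_set - set(model.markers)
    if missing:
        raise DimensionMismatchError(f"markers not in typing model: {sorted(missing)}")
    if len(measured_table) != len(imputed_table):
        raise DimensionMismatchError("measured and imputed tables misaligned")
    n = len(measured_table)
    x = np.empty((n, len(model.markers)))
    for j, m in enumerate(model.markers):
        source = measured_table if m in measured_set else imputed_table
        col = NORM_PREFIX + m
        if col not in source.df.columns:
            raise DimensionMismatchError(f"missing column {col}")
        x[:, j] = source.df[col].to_numpy(dtype=float)
    return model.classify(model.project(x))
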