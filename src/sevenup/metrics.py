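"""Patchwise evaluation and spatial-adjacency comparison.

Cell-to-cell expression in a tissue is noisy even between neighbors, so
fidelity is judged on regular spatial tiles ("patches") rather than single
cells:

- patchwise PCC — per marker, average the measured and the predicted
  values within each non-empty patch and correlate the patch means;
- patchwise F1 — per cell type, call a patch positive when at least one
  cell of the type is present, compute F1 over patches, and weight the
  per-type scores by their true-positive-patch counts;
- adjacency matrix — relative frequencies of spatially adjacent cell-type
  pairs on a k-nearest-neighbor spatial graph (k = 5 by default),
  symmetric with grand sum 1, compared by elementwise RMSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sevenup.exceptions import (
    DimensionMismatchError,
    SevenUpError,
    UndefinedCorrelationError,
)
from sevenup.celltype import knn_graph_edges

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 128  # px
ADJACENCY_K = 5


@dataclass(frozen=True)
class PatchGrid:
    """Cell → patch assignment on a regular grid over the sample.

    Cells are binned by centroid; the sample id participates in the patch
    key so patches never span samples.  Every cell maps to exactly one
    patch.
    """

    patch_size_px: int
    patch_ids: np.ndarray  # dense integer patch index per cell

    @classmethod
    def from_centroids(
        cls,
        centroid_x: np.ndarray,
        centroid_y: np.ndarray,
        sample_ids: np.ndarray | None = None,
        patch_size_px: int = DEFAULT_PATCH_SIZE,
    ) -> "PatchGrid":
        if patch_size_px < 1:
            raise SevenUpError("patch size must be >= 1 px")
        gx = (np.asarray(centroid_x, dtype=float) // patch_size_px).astype(np.int64)
        gy = (np.asarray(centroid_y, dtype=float) // patch_size_px).astype(np.int64)
        if sample_ids is None:
            sample_ids = np.zeros(len(gx), dtype=object)
        key = pd.MultiIndex.from_arrays([np.asarray(sample_ids, dtype=object), gy, gx])
        codes = pd.factorize(key)[0]
        return cls(patch_size_px=patch_size_px, patch_ids=codes.astype(np.int64))

    @property
    def n_patches(self) -> int:
        return int(self.patch_ids.max()) + 1 if len(self.patch_ids) else 0


def _patch_means(values: np.ndarray, grid: PatchGrid) -> np.ndarray:
    sums = np.bincount(grid.patch_ids, weights=values, minlength=grid.n_patches)
    counts = np.bincount(grid.patch_ids, minlength=grid.n_patches)
    return sums / counts  # every patch id is occupied by construction


def patchwise_pcc(
    measured: np.ndarray,
    predicted: np.ndarray,
    grid: PatchGrid,
) -> float:
    """Pearson correlation of patch-mean measured vs. predicted values.

    Raises :class:`UndefinedCorrelationError` if either patch-mean vector
    has zero variance, rather than propagating NaN.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or len(measured) != len(grid.patch_ids):
        raise DimensionMismatchError("measured/predicted not aligned with the grid")
    if grid.n_patches < 2:
        raise SevenUpError("patchwise PCC needs >= 2 non-empty patches")
    a = _patch_means(measured, grid)
    b = _patch_means(predicted, grid)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in patch-mean vector")
    return float(stats.pearsonr(a, b).statistic)


def patchwise_pcc_table(
    measured: np.ndarray, predicted: np.ndarray, grid: PatchGrid, markers: list[str]
) -> dict[str, float]:
    """Per-marker patchwise PCC for cells × markers matrices."""
    return {
        m: patchwise_pcc(measured[:, j], predicted[:, j], grid)
        for j, m in enumerate(markers)
    }


def patchwise_f1(
    true_types: np.ndarray,
    predicted_types: np.ndarray,
    grid: PatchGrid,
) -> tuple[dict[str, float], float]:
    """Per-type patch-presence F1 and the weighted mean.

    A patch is positive for a type iff at least one of its cells carries
    the type; weights are the per-type true-positive-patch counts (true
    support).  A type never predicted scores 0 with a logged notice.
    """
    true_types = np.asarray(true_types, dtype=object)
    predicted_types = np.asarray(predicted_types, dtype=object)
    if len(true_types) != len(predicted_types) or len(true_types) != len(grid.patch_ids):
        raise DimensionMismatchError("type vectors not aligned with the grid")
    types = sorted(set(true_types.tolist()) | set(predicted_types.tolist()))
    per_type: dict[str, float] = {}
    weights: dict[str, int] = {}
    for t in types:
        pos_true = np.unique(grid.patch_ids[true_types == t])
        pos_pred = np.unique(grid.patch_ids[predicted_types == t])
        tp = len(np.intersect1d(pos_true, pos_pred, assume_unique=True))
        fp = len(pos_pred) - tp
        fn = len(pos_true) - tp
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if len(pos_pred) == 0:
            logger.info("type %r never predicted; F1 = 0", t)
        per_type[str(t)] = float(f1)
        weights[str(t)] = len(pos_true)
    total = sum(weights.values())
    weighted = (
        sum(per_type[t] * weights[t] for t in per_type) / total if total else 0.0
    )
    return per_type, float(weighted)


def adjacency_matrix(
    centroid_x: np.ndarray,
    centroid_y: np.ndarray,
    types: np.ndarray,
    type_order: list[str],
    k: int = ADJACENCY_K,
) -> np.ndarray:
    """Relative frequencies of spatially adjacent type pairs.

    The spatial graph is a union-symmetrized kNN graph on centroids; each
    unordered edge contributes once, split over the symmetric (a, b)/(b, a)
    entries.  The matrix is symmetric with grand sum 1.
    """
    types = np.asarray(types, dtype=object)
    if len(centroid_x) < 2:
        raise SevenUpError("adjacency matrix needs >= 2 cells")
    unknown = set(types.tolist()) - set(type_order)
    if unknown:
        raise DimensionMismatchError(f"types not in type_order: {sorted(unknown)}")
    coords = np.stack([np.asarray(centroid_x, float), np.asarray(centroid_y, float)], axis=1)
    edges = knn_graph_edges(coords, k)
    code = {t: i for i, t in enumerate(type_order)}
    ta = np.array([code[t] for t in types[edges[:, 0]]])
    tb = np.array([code[t] for t in types[edges[:, 1]]])
    n_t = len(type_order)
    mat = np.zeros((n_t, n_t))
    np.add.at(mat, (ta, tb), 0.5)
    np.add.at(mat, (tb, ta), 0.5)
    return mat / mat.sum()


def adjacency_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square elementwise distance between two adjacency matrices."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def patch_size_sweep(
    measured: np.ndarray,
    predicted: np.ndarray,
    centroid_x: np.ndarray,
    centroid_y: np.ndarray,
    sample_ids: np.ndarray,
    markers: list[str],
    patch_sizes: list[int],
    true_types: np.ndarray | None = None,
    predicted_types: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean patchwise PCC (and weighted F1, when types are given) as a
    function of patch size; a reporting utility with no asserted trend."""
    rows = []
    for size in patch_sizes:
        grid = PatchGrid.from_centroids(centroid_x, centroid_y, sample_ids, size)
        table = patchwise_pcc_table(measured, predicted, grid, markers)
        row = {"patch_size_px": size, "mean_pcc": float(np.mean(list(table.values())))}
        if true_types is not None and predicted_types is not None:
            _, row["weighted_f1"] = patchwise_f1(true_types, predicted_types, grid)
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_ci(
    per_patch_statistic, n_patches: int, n_boot: int = 200, alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap over patches.

    ``per_patch_statistic(patch_indices) -> float`` recomputes the metric
    on a resampled patch multiset.  Patch-level resampling is a convention
    choice; it is reported with results, not asserted against anything.
    """
    rng = np.random.default_rng(seed)
    vals = [
        per_patch_statistic(rng.integers(0, n_patches, size=n_patches))
        for _ in range(n_boot)
    ]
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
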