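"""Patchwise PCC / F1 and adjacency-matrix comparisons."""

import numpy as np
import pytest
from scipy import stats

from sevenup.exceptions import SevenUpError, UndefinedCorrelationError
from sevenup.metrics import (
    PatchGrid,
    adjacency_matrix,
    adjacency_rmsd,
    patchwise_f1,
    patchwise_pcc,
)


def _random_grid(n_cells=100, patch_size=50, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 500, n_cells)
    y = rng.uniform(0, 500, n_cells)
    return rng, PatchGrid.from_centroids(x, y, patch_size_px=patch_size)


class TestPatchGrid:
    def test_every_cell_maps_to_exactly_one_patch(self):
        _, grid = _random_grid()
        assert grid.patch_ids.shape == (100,)
        assert (grid.patch_ids >= 0).all()

    def test_patches_do_not_span_samples(self):
        x = np.array([10.0, 10.0])
        y = np.array([10.0, 10.0])
        grid = PatchGrid.from_centroids(x, y, np.array(["s1", "s2"]), 128)
        assert grid.patch_ids[0] != grid.patch_ids[1]


class TestPatchwisePcc:
    def test_identity_prediction_scores_one(self):
        rng, grid = _random_grid()
        v = rng.normal(size=100)
        assert patchwise_pcc(v, v, grid) == pytest.approx(1.0)

    def test_exact_anticorrelation_scores_minus_one(self):
        x = np.arange(4, dtype=float) * 100 + 50
        grid = PatchGrid.from_centroids(x, np.zeros(4), patch_size_px=100)
        measured = np.array([1.0, 2.0, 3.0, 4.0])
        predicted = np.array([4.0, 3.0, 2.0, 1.0])
        assert patchwise_pcc(measured, predicted, grid) == pytest.approx(-1.0)

    def test_matches_brute_force_group_average_oracle(self):
        """20 patches x 5 cells: independent group-average-correlate to 1e-12."""
        rng = np.random.default_rng(42)
        patch_x = np.repeat(np.arange(20), 5) * 64 + 32
        jitter = rng.uniform(-20, 20, 100)
        x = patch_x + jitter
        y = rng.uniform(0, 60, 100)
        grid = PatchGrid.from_centroids(x, y, patch_size_px=64)
        measured = rng.normal(size=100)
        predicted = measured + rng.normal(0, 0.5, 100)
        got = patchwise_pcc(measured, predicted, grid)
        # oracle: dict-based grouping, plain means, scipy correlation
        groups = {}
        for xi, m, p in zip(x, measured, predicted):
            groups.setdefault(int(xi // 64), []).append((m, p))
        a = [np.mean([m for m, _ in v]) for _, v in sorted(groups.items())]
        b = [np.mean([p for _, p in v]) for _, v in sorted(groups.items())]
        expected = stats.pearsonr(a, b).statistic
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_pixel_patches_degenerate_to_per_cell_pcc(self):
        rng = np.random.default_rng(3)
        x = np.arange(50, dtype=float)  # distinct 1-px patches
        grid = PatchGrid.from_centroids(x, np.zeros(50), patch_size_px=1)
        m = rng.normal(size=50)
        p = m + rng.normal(0, 1, 50)
        assert patchwise_pcc(m, p, grid) == pytest.approx(
            stats.pearsonr(m, p).statistic, abs=1e-12
        )

    def test_zero_variance_raises_not_nan(self):
        _, grid = _random_grid()
        with pytest.raises(UndefinedCorrelationError):
            patchwise_pcc(np.ones(100), np.arange(100.0), grid)

    def test_needs_two_patches(self):
        grid = PatchGrid.from_centroids(np.zeros(5), np.zeros(5), patch_size_px=100)
        with pytest.raises(SevenUpError):
            patchwise_pcc(np.arange(5.0), np.arange(5.0), grid)


class TestPatchwiseF1:
    def test_identical_type_maps_score_one(self):
        rng, grid = _random_grid()
        types = rng.choice(["a", "b", "c"], 100)
        per_type, weighted = patchwise_f1(types, types, grid)
        assert weighted == 1.0
        assert all(v == 1.0 for v in per_type.values())

    def test_never_predicted_type_scores_zero(self):
        rng, grid = _random_grid()
        truth = np.array(["a"] * 50 + ["b"] * 50)
        pred = np.array(["a"] * 100)
        per_type, _ = patchwise_f1(truth, pred, grid)
        assert per_type["b"] == 0.0

    def test_three_patch_enumeration_gives_half(self):
        """Type positive in patches {1,2} truly, {2,3} predicted:
        TP=1, FP=1, FN=1 so F1 = 0.5 exactly."""
        x = np.array([50.0, 150.0, 250.0])
        grid = PatchGrid.from_centroids(x, np.zeros(3), patch_size_px=100)
        truth = np.array(["A", "A", "other"])
        pred = np.array(["other", "A", "A"])
        per_type, _ = patchwise_f1(truth, pred, grid)
        assert per_type["A"] == pytest.approx(0.5)

    def test_invariant_to_cell_ordering(self):
        rng, grid = _random_grid(seed=7)
        types = rng.choice(["a", "b"], 100)
        pred = rng.choice(["a", "b"], 100)
        perm = rng.permutation(100)
        grid_p = PatchGrid(grid.patch_size_px, grid.patch_ids[perm])
        _, w1 = patchwise_f1(types, pred, grid)
        _, w2 = patchwise_f1(types[perm], pred[perm], grid_p)
        assert w1 == pytest.approx(w2)


class TestAdjacency:
    def test_identity_rmsd_zero_and_sum_one(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 300, 80), rng.uniform(0, 300, 80)
        types = rng.choice(["a", "b", "c"], 80)
        mat = adjacency_matrix(x, y, types, ["a", "b", "c"])
        assert mat.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        assert adjacency_rmsd(mat, mat) == 0.0

    def test_alternating_line_is_off_diagonal_dominant(self):
        """Six cells alternating a/b on a line with k=1 neighbors: every
        spatial edge joins unlike types, enumerable by hand."""
        x = np.arange(6, dtype=float) * 10
        types = np.array(["a", "b", "a", "b", "a", "b"])
        mat = adjacency_matrix(x, np.zeros(6), types, ["a", "b"], k=1)
        # k=1 symmetrized graph on a line = the 5 consecutive edges; all a-b
        assert mat[0, 0] == 0.0 and mat[1, 1] == 0.0
        assert mat[0, 1] == pytest.approx(0.5)
        assert mat[1, 0] == pytest.approx(0.5)

    def test_type_relabeling_permutes_matrix(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(0, 200, 60), rng.uniform(0, 200, 60)
        types = rng.choice(["a", "b"], 60)
        m1 = adjacency_matrix(x, y, types, ["a", "b"])
        m2 = adjacency_matrix(x, y, types, ["b", "a"])
        np.testing.assert_allclose(m1, m2[::-1, ::-1], atol=1e-12)

    def test_rmsd_shape_mismatch(self):
        with pytest.raises(SevenUpError):
            adjacency_rmsd(np.zeros((2, 2)), np.zeros((3, 3)))
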