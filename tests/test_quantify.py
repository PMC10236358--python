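"""Quantification: background correction, dilation, means, normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cell_table
from sevenup.exceptions import (
    DegenerateDispersionError,
    NoCellsError,
    SevenUpError,
)
from sevenup.io_formats import CellTable, MarkerImageStack, SegmentationMask
from sevenup.quantify import (
    background_correct,
    dilate_mask,
    mean_expression,
    normalize,
)


def _stack_with_blanks(value, blank_first, blank_last, cycle, n_cycles):
    img = np.full((8, 8), float(value))
    return MarkerImageStack(
        channels={"A": img},
        cycle_index={"A": cycle},
        n_cycles=n_cycles,
        blank_first=np.full((8, 8), float(blank_first)),
        blank_last=np.full((8, 8), float(blank_last)),
    )


class TestBackgroundCorrect:
    @pytest.mark.parametrize(
        "cycle,n_cycles,expected",
        [
            (0, 3, 10 - 4),  # first cycle: exactly blank_first
            (2, 3, 10 - 8),  # last cycle: exactly blank_last
            (1, 3, 10 - 6),  # middle cycle: w=0.5 blend of 4 and 8
        ],
    )
    def test_cycle_interpolated_subtraction(self, cycle, n_cycles, expected):
        out = background_correct(_stack_with_blanks(10, 4, 8, cycle, n_cycles))
        np.testing.assert_allclose(out.channels["A"], expected)

    def test_result_clipped_at_zero(self):
        out = background_correct(_stack_with_blanks(3, 5, 5, 0, 2))
        assert (out.channels["A"] == 0).all()

    def test_no_blanks_is_identity(self):
        stack = MarkerImageStack(channels={"A": np.full((4, 4), 7.0)})
        out = background_correct(stack)
        np.testing.assert_array_equal(out.channels["A"], stack.channels["A"])


class TestDilateMask:
    def test_zero_iterations_is_identity(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[4, 4] = 1
        out = dilate_mask(SegmentationMask(labels), iterations=0, seed=0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_isolated_background_never_flips(self):
        """A pixel with zero labeled neighbors has flip probability 0."""
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[0, 0] = 1
        out = dilate_mask(SegmentationMask(labels), iterations=1, seed=0)
        assert out.labels[5:, 5:].sum() == 0

    def test_fully_surrounded_pixel_flips_with_probability_one(self):
        labels = np.ones((3, 3), dtype=np.int32)
        labels[1, 1] = 0
        for seed in range(5):
            out = dilate_mask(SegmentationMask(labels), iterations=1, seed=seed)
            assert out.labels[1, 1] == 1

    def test_cell_pixels_never_revert_or_overwrite(self):
        labels = np.zeros((15, 15), dtype=np.int32)
        labels[3, 3] = 1
        labels[3, 6] = 2
        out = dilate_mask(SegmentationMask(labels), iterations=5, seed=4)
        assert out.labels[3, 3] == 1 and out.labels[3, 6] == 2
        # every original label survives and no third label appears
        assert set(np.unique(out.labels)) <= {0, 1, 2}

    def test_expected_area_nondecreasing_in_iterations(self):
        labels = np.zeros((21, 21), dtype=np.int32)
        labels[10, 10] = 1
        areas = []
        for its in range(0, 10, 3):
            sizes = [
                (dilate_mask(SegmentationMask(labels), its, seed=s).labels > 0).sum()
                for s in range(30)
            ]
            areas.append(np.mean(sizes))
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


class TestMeanExpression:
    def test_uniform_channel_gives_constant_means(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[1:3, 1:3] = 1
        labels[6:9, 6:9] = 2
        stack = MarkerImageStack(channels={"A": np.full((10, 10), 3.5)})
        table = mean_expression(stack, SegmentationMask(labels))
        np.testing.assert_allclose(table.df["raw_A"], 3.5)

    def test_hand_computed_two_cell_means(self):
        labels = np.zeros((1, 5), dtype=np.int32)
        labels[0, :2] = 1
        labels[0, 2:] = 2
        img = np.array([[1.0, 3.0, 2.0, 2.0, 5.0]])
        table = mean_expression(
            MarkerImageStack(channels={"A": img}), SegmentationMask(labels)
        )
        np.testing.assert_allclose(table.df["raw_A"], [2.0, 3.0])

    def test_centroids_are_label_pixel_centroids(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:4, 4:8] = 1  # rows 2-3, cols 4-7
        table = mean_expression(
            MarkerImageStack(channels={"A": np.zeros((10, 10))}),
            SegmentationMask(labels),
        )
        assert table.df.loc[0, "centroid_y"] == pytest.approx(2.5)
        assert table.df.loc[0, "centroid_x"] == pytest.approx(5.5)

    def test_empty_mask_raises(self):
        with pytest.raises(NoCellsError):
            mean_expression(
                MarkerImageStack(channels={"A": np.zeros((4, 4))}),
                SegmentationMask(np.zeros((4, 4), dtype=np.int32)),
            )


class TestNormalize:
    def test_matches_independent_arcsinh_zscore_script(self):
        """x = 1..10: q0.2 = 2.8 by linear interpolation; element-wise match
        with a from-scratch oracle to 1e-12."""
        df = pd.DataFrame(
            {
                "sample_id": "s",
                "cell_label": np.arange(1, 11, dtype=np.int64),
                "coverslip_id": "c",
                "centroid_x": 0.0,
                "centroid_y": 0.0,
                "raw_A": np.arange(1, 11, dtype=float),
            }
        )
        out, stats = normalize(CellTable(df))
        # independent oracle: plain arithmetic, no package code
        x = np.arange(1, 11, dtype=float)
        q20 = 2.8  # 20th percentile of 1..10, linear interpolation
        y = np.arcsinh(x / (5 * q20))
        expected = (y - y.mean()) / y.std()
        np.testing.assert_allclose(
            out.df["norm_A"].to_numpy(), expected, atol=1e-12
        )
        assert stats.get("s", "A")["q20"] == pytest.approx(2.8)

    def test_normalized_columns_have_zero_mean_unit_sd(self):
        table = make_cell_table(50, markers=("A", "B"), seed=5)
        out, _ = normalize(table)
        for m in ("A", "B"):
            col = out.df[f"norm_{m}"]
            assert col.mean() == pytest.approx(0.0, abs=1e-9)
            assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_stats_are_per_sample_never_pooled(self):
        t1 = make_cell_table(30, seed=1, sample_id="s1")
        t2 = make_cell_table(30, seed=2, sample_id="s2")
        t2.df["raw_A"] *= 10  # very different scale
        combined = CellTable(pd.concat([t1.df, t2.df], ignore_index=True))
        out, _ = normalize(combined)
        for sid in ("s1", "s2"):
            sub = out.df[out.df["sample_id"] == sid]
            assert sub["norm_A"].mean() == pytest.approx(0.0, abs=1e-9)
            assert sub["norm_A"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_applying_stored_stats_reproduces_training_values(self):
        table = make_cell_table(40, seed=3)
        out, stats = normalize(table)
        again, _ = normalize(table, stats=stats)
        np.testing.assert_allclose(
            again.df["norm_A"].to_numpy(), out.df["norm_A"].to_numpy(), atol=1e-12
        )

    def test_constant_marker_is_degenerate(self):
        table = make_cell_table(10)
        table.df["raw_A"] = 4.0
        with pytest.raises(DegenerateDispersionError):
            normalize(table)

    def test_zero_q20_falls_back_to_smallest_positive(self):
        table = make_cell_table(10)
        x = np.zeros(10)
        x[-3:] = [0.5, 2.0, 4.0]  # q0.2 = 0, smallest positive 0.5
        table.df["raw_A"] = x
        out, stats = normalize(table)
        assert stats.get("s0", "A")["divisor"] == pytest.approx(0.5)
        assert np.isfinite(out.df["norm_A"]).all()

    def test_single_cell_sample_rejected(self):
        with pytest.raises(SevenUpError):
            normalize(make_cell_table(1))
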