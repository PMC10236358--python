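"""Gradient-boosted imputation: fidelity, determinism, persistence, splits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from sevenup.exceptions import (
    CorruptBundleError,
    DimensionMismatchError,
    MissingMarkerError,
)
from sevenup.impute import (
    ImputationBundle,
    ImputerHyperparams,
    fit_imputer,
    impute,
    split_by_coverslip,
)
from sevenup.io_formats import CellTable, PanelManifest


def _table_with_targets(n=400, seed=0, target="copy"):
    """Normalized measured markers A,B plus a target C defined from them."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    if target == "copy":
        c = a.copy()
    else:
        c = (a + b) / np.sqrt(2)
    df = pd.DataFrame(
        {
            "sample_id": "s0",
            "cell_label": np.arange(1, n + 1, dtype=np.int64),
            "coverslip_id": np.where(np.arange(n) < n // 2, "c0", "c1"),
            "centroid_x": 0.0,
            "centroid_y": 0.0,
            "norm_A": a,
            "norm_B": b,
            "norm_C": c,
        }
    )
    manifest = PanelManifest(("A", "B", "C"), ("A", "B"))
    return CellTable(df), manifest


def test_copied_marker_imputes_nearly_perfectly():
    table, manifest = _table_with_targets(n=1200, target="copy")
    train = table.subset(table.df["coverslip_id"] == "c0")
    test = table.subset(table.df["coverslip_id"] == "c1")
    bundle = fit_imputer(train, manifest, seed=0)
    out = impute(bundle, test)
    r = pearsonr(test.df["norm_C"], out.df["norm_C"]).statistic
    assert r >= 0.99


def test_default_hyperparameters():
    hp = ImputerHyperparams()
    assert (hp.learning_rate, hp.n_estimators, hp.max_depth, hp.colsample_bytree) == (
        0.1, 500, 3, 0.7,
    )
    assert hp.objective == "reg:squarederror"


def test_measured_columns_untouched_and_deterministic():
    table, manifest = _table_with_targets(target="mix")
    bundle = fit_imputer(table, manifest, seed=1)
    stripped = CellTable(table.df.drop(columns=["norm_C"]))
    out1 = impute(bundle, stripped)
    out2 = impute(bundle, stripped)
    np.testing.assert_array_equal(out1.df["norm_A"], table.df["norm_A"])
    np.testing.assert_array_equal(out1.df["norm_C"], out2.df["norm_C"])


def test_zero_row_table_gives_zero_row_full_schema():
    table, manifest = _table_with_targets()
    bundle = fit_imputer(table, manifest, seed=0)
    empty = CellTable(table.df.iloc[:0].drop(columns=["norm_C"]))
    out = impute(bundle, empty)
    assert len(out) == 0
    assert "norm_C" in out.df.columns


def test_row_permutation_permutes_outputs():
    table, manifest = _table_with_targets(target="mix")
    bundle = fit_imputer(table, manifest, seed=0)
    out = impute(bundle, table)
    rng = np.random.default_rng(4)
    perm = rng.permutation(len(table))
    permuted = CellTable(table.df.iloc[perm].reset_index(drop=True))
    out_p = impute(bundle, permuted)
    np.testing.assert_allclose(
        out_p.df["norm_C"].to_numpy(), out.df["norm_C"].to_numpy()[perm]
    )


def test_missing_target_column_raises():
    table, manifest = _table_with_targets()
    broken = CellTable(table.df.drop(columns=["norm_C"]))
    with pytest.raises(MissingMarkerError):
        fit_imputer(broken, manifest)


def test_feature_row_misalignment_raises():
    table, manifest = _table_with_targets()
    with pytest.raises(DimensionMismatchError):
        fit_imputer(table, manifest, features=np.zeros((7, 2)))


def test_shape_driven_marker_needs_morphology_features():
    """A marker that is a pure function of eccentricity, with identical
    expression means across types: the expression-only imputer is at its
    Bayes limit of zero correlation, while morphology probabilities make
    the target well-predictable."""
    from scipy.stats import pearsonr as _pearsonr

    from sevenup.featurizer import (
        FeaturizerConfig,
        morphology_features,
        train_featurizer,
    )
    from sevenup.patches import PatchConfig, extract_patches
    from sevenup.quantify import normalize
    from sevenup.synthetic import (
        CellTypeSpec,
        TissueRecipe,
        generate_coverslips,
        with_shape_marker,
    )

    mu = {"A": 3.0, "B": 3.0}
    types = (
        CellTypeSpec(name="round", prevalence=0.5, radius=4.0,
                     mean_expression=mu, expression_sd=0.3),
        CellTypeSpec(name="long", prevalence=0.5, shape="ellipse", radius=5.0,
                     eccentricity=(0.93, 0.97), mean_expression=mu,
                     expression_sd=0.3),
    )
    recipe = TissueRecipe(
        markers=("A", "B"), n_cells=260, image_size=(420, 420),
        cell_types=types, noise_sd=0.1, seed=3,
    )
    recipe = with_shape_marker(recipe, "S", 1.0, 6.0)
    samples, truth = generate_coverslips(recipe, [0.0, 0.2, 0.4])
    table, _ = normalize(truth)
    manifest = PanelManifest(("A", "B", "S"), ("A", "B"))
    patches, labels = {}, {}
    for k, (stack, mask) in enumerate(samples):
        sub = table.df[table.df.sample_id == f"S{k}"]
        patches[k] = extract_patches(
            stack, mask, sub.cell_label.tolist(), ("A", "B"), PatchConfig()
        )
        labels[k] = sub.cell_type.to_numpy()
    cfg = FeaturizerConfig(
        n_members=1, width=8, input_size=32, batch_size=64,
        learning_rate=1e-2, eval_every=50, max_steps=400,
        plateau_evals=5, stop_evals=8, seed=0,
    )
    ensemble = train_featurizer(patches[0], labels[0], patches[1], labels[1], cfg)
    feats = np.vstack([morphology_features(ensemble, patches[k]) for k in range(3)])
    tr = (table.df.sample_id == "S0").to_numpy()
    te = (table.df.sample_id == "S2").to_numpy()
    train_t, test_t = table.subset(tr), table.subset(te)

    def heldout_pcc(f):
        bundle = fit_imputer(train_t, manifest, f[tr] if f is not None else None, seed=0)
        out = impute(bundle, test_t, f[te] if f is not None else None)
        return _pearsonr(test_t.df["norm_S"], out.df["norm_S"]).statistic

    assert heldout_pcc(None) <= 0.1
    assert heldout_pcc(feats) >= 0.5


class TestBundlePersistence:
    def test_save_load_bit_identical_imputation(self, tmp_path):
        table, manifest = _table_with_targets(target="mix")
        bundle = fit_imputer(table, manifest, seed=3)
        before = impute(bundle, table).df["norm_C"].to_numpy()
        path = tmp_path / "bundle.zip"
        bundle.save(path)
        loaded = ImputationBundle.load(path)
        after = impute(loaded, table).df["norm_C"].to_numpy()
        np.testing.assert_array_equal(before, after)
        assert loaded.feature_spec == bundle.feature_spec

    def test_truncated_archive_is_corrupt(self, tmp_path):
        table, manifest = _table_with_targets()
        bundle = fit_imputer(table, manifest, seed=0)
        path = tmp_path / "bundle.zip"
        bundle.save(path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(CorruptBundleError):
            ImputationBundle.load(path)

    def test_feature_width_mismatch_rejected(self, tmp_path):
        table, manifest = _table_with_targets()
        bundle = fit_imputer(table, manifest, features=np.zeros((len(table), 3)), seed=0)
        with pytest.raises(DimensionMismatchError):
            impute(bundle, table, features=None)


class TestSplitByCoverslip:
    def test_auto_assigns_largest_to_train(self):
        slips = np.array(["a"] * 50 + ["b"] * 30 + ["c"] * 20)
        masks = split_by_coverslip(slips, "auto")
        assert masks["train"].sum() == 50
        assert masks["val"].sum() == 30
        assert masks["test"].sum() == 20
        assert not (masks["train"] & masks["test"]).any()

    def test_explicit_overlap_rejected(self):
        slips = np.array(["a", "b"])
        with pytest.raises(DimensionMismatchError):
            split_by_coverslip(slips, {"train": ["a"], "val": ["a"], "test": ["b"]})

    def test_unknown_coverslip_rejected(self):
        slips = np.array(["a", "b"])
        with pytest.raises(DimensionMismatchError):
            split_by_coverslip(slips, {"train": ["a"], "val": ["b"], "test": ["z"]})


def test_bundle_carries_featurizer_weights(tmp_path):
    """One archive holds manifest, regressors and the featurizer ensemble."""
    from test_featurizer import FAST, make_shape_patches

    from sevenup.featurizer import FeaturizerConfig, train_featurizer

    x, y = make_shape_patches(80, seed=0)
    cfg = FeaturizerConfig(n_members=1, seed=0, **{**FAST, "max_steps": 30})
    ensemble = train_featurizer(x, y, x, y, cfg)
    table, manifest = _table_with_targets(n=200)
    bundle = fit_imputer(table, manifest, seed=0)
    bundle.featurizer = ensemble
    path = tmp_path / "b.zip"
    bundle.save(path)
    loaded = ImputationBundle.load(path)
    np.testing.assert_array_equal(
        loaded.featurizer.predict_proba(x), ensemble.predict_proba(x)
    )
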