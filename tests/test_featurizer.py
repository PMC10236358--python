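"""Featurizer ensemble: training protocol, probability outputs, determinism."""

import numpy as np
import pytest
from sklearn.metrics import f1_score

from sevenup import _nn
from sevenup.exceptions import DimensionMismatchError, SevenUpError
from sevenup.featurizer import (
    FeaturizerConfig,
    FeaturizerEnsemble,
    morphology_features,
    train_featurizer,
)


def make_shape_patches(n, noise=0.0, seed=0, size=32):
    """Disks vs bars: Bayes-separable by shape, identical total intensity."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n, 3, size, size), dtype=np.float32)
    labels = np.array(["disk", "bar"])[rng.integers(0, 2, n)]
    for i, lab in enumerate(labels):
        cy, cx = rng.integers(10, size - 10, 2)
        if lab == "disk":
            yy, xx = np.mgrid[:size, :size]
            x[i, 0][(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] = 0.6
        else:
            x[i, 0, cy - 1 : cy + 1, cx - 7 : cx + 7] = 0.6
        x[i, 1] = 0.2  # uninformative context channels
        x[i, 2] = 0.2
    if noise:
        x += rng.normal(0, noise, x.shape).astype(np.float32)
    return np.clip(x, 0, 1), labels


FAST = dict(width=8, input_size=32, batch_size=32, learning_rate=1e-2,
            eval_every=25, max_steps=200, plateau_evals=4, stop_evals=8)


@pytest.fixture(scope="module")
def separable_ensemble():
    x, y = make_shape_patches(240, seed=0)
    xv, yv = make_shape_patches(120, seed=1)
    cfg = FeaturizerConfig(n_members=2, seed=0, **FAST)
    return train_featurizer(x, y, xv, yv, cfg), (xv, yv)


def test_shape_separable_classes_reach_high_validation_f1(separable_ensemble):
    """Disks vs bars are Bayes-separable; any competent classifier nears 1."""
    ensemble, _ = separable_ensemble
    best = [max(f for _, f in log) for log in ensemble.training_logs]
    assert all(f >= 0.95 for f in best)


def test_member_probabilities_sum_to_one(separable_ensemble):
    ensemble, (xv, _) = separable_ensemble
    for m in range(len(ensemble.members)):
        probs = ensemble.member_proba(m, xv)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_ensemble_mean_is_probability_vector(separable_ensemble):
    ensemble, (xv, _) = separable_ensemble
    feats = morphology_features(ensemble, xv)
    assert feats.shape == (len(xv), 2)
    assert (feats >= 0).all()
    np.testing.assert_allclose(feats.sum(axis=1), 1.0, atol=1e-6)


def test_feature_argmax_reproduces_validation_f1(separable_ensemble):
    """Recomputing F1 from saved predictions matches the training log."""
    ensemble, (xv, yv) = separable_ensemble
    feats = morphology_features(ensemble, xv)
    pred = np.array(ensemble.class_names)[feats.argmax(axis=1)]
    f1 = f1_score(yv, pred, average="weighted")
    best = max(max(f for _, f in log) for log in ensemble.training_logs)
    assert f1 >= best - 0.01


def test_training_reproducible_given_seed():
    x, y = make_shape_patches(120, seed=2)
    xv, yv = make_shape_patches(60, seed=3)
    cfg = FeaturizerConfig(n_members=1, seed=7, **{**FAST, "max_steps": 75})
    e1 = train_featurizer(x, y, xv, yv, cfg)
    e2 = train_featurizer(x, y, xv, yv, cfg)
    assert e1.training_logs == e2.training_logs
    for p1, p2 in zip(e1.members[0].params(), e2.members[0].params()):
        np.testing.assert_array_equal(p1, p2)


def test_identical_member_seeds_give_identical_weights():
    """Members differ only by their init seed; with one member the ensemble
    mean trivially equals the member output."""
    x, y = make_shape_patches(120, seed=2)
    xv, yv = make_shape_patches(60, seed=3)
    cfg = FeaturizerConfig(n_members=1, seed=7, **{**FAST, "max_steps": 50})
    ensemble = train_featurizer(x, y, xv, yv, cfg)
    np.testing.assert_allclose(
        morphology_features(ensemble, xv), ensemble.member_proba(0, xv), atol=1e-7
    )


def test_ensemble_f1_at_least_mean_member_f1_on_noisy_benchmark():
    """Averaging the members' probabilities tends to beat the average member
    (checked as a mean over several independent runs, not per run)."""
    ens_scores, member_scores = [], []
    for run in range(5):
        x, y = make_shape_patches(150, noise=0.35, seed=10 + run)
        xv, yv = make_shape_patches(100, noise=0.35, seed=100 + run)
        cfg = FeaturizerConfig(
            n_members=3, seed=run, **{**FAST, "max_steps": 100, "eval_every": 100}
        )
        ensemble = train_featurizer(x, y, xv, yv, cfg)
        feats = morphology_features(ensemble, xv)
        pred = np.array(ensemble.class_names)[feats.argmax(axis=1)]
        ens_scores.append(f1_score(yv, pred, average="weighted"))
        per_member = []
        for m in range(3):
            pm = np.array(ensemble.class_names)[
                ensemble.member_proba(m, xv).argmax(axis=1)
            ]
            per_member.append(f1_score(yv, pm, average="weighted"))
        member_scores.append(np.mean(per_member))
    assert np.mean(ens_scores) >= np.mean(member_scores) - 1e-9


def test_untrained_symmetric_ensemble_outputs_near_uniform():
    rng = np.random.default_rng(0)
    members = [
        _nn.small_cnn(3, 4, np.random.default_rng(s), input_size=32, width=8)
        for s in range(3)
    ]
    # zero the final layer: the symmetric-initialization limit
    for m in members:
        m.layers[-1].w[...] = 0.0
        m.layers[-1].b[...] = 0.0
    ensemble = FeaturizerEnsemble(
        members=members, class_names=("a", "b", "c", "d"),
        input_depth=3, input_size=32, width=8,
    )
    x = rng.random((10, 3, 32, 32)).astype(np.float32)
    feats = morphology_features(ensemble, x)
    np.testing.assert_allclose(feats, 0.25, atol=1e-6)


def test_single_class_training_set_rejected():
    x, _ = make_shape_patches(60, seed=0)
    y = np.array(["only"] * 60)
    with pytest.raises(SevenUpError):
        train_featurizer(x, y, x, y, FeaturizerConfig(n_members=1, **FAST))


def test_depth_mismatch_rejected(separable_ensemble):
    ensemble, _ = separable_ensemble
    with pytest.raises(DimensionMismatchError):
        morphology_features(ensemble, np.zeros((4, 5, 32, 32), dtype=np.float32))


def test_save_load_round_trip(tmp_path, separable_ensemble):
    ensemble, (xv, _) = separable_ensemble
    path = tmp_path / "ensemble.npz"
    ensemble.save(path)
    loaded = FeaturizerEnsemble.load(path)
    np.testing.assert_array_equal(
        morphology_features(ensemble, xv), morphology_features(loaded, xv)
    )
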