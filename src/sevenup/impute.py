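"""Gradient-boosted imputation of the unmeasured markers.

One boosted-tree regressor per imputed marker, all sharing one feature
matrix: the P measured markers' normalized expressions, optionally
concatenated with the morphology probability vector from the featurizer
ensemble.  Joint prediction of the remaining panel under squared error
decomposes exactly into these independent per-target fits.

Hyperparameters default to: learning rate 0.1, 500 estimators, max depth
3, per-tree column sampling 0.7, squared-error objective.

Coverslip-grouped splitting lives here (``split_by_coverslip``) and is
reused by the featurizer: evaluation is always on held-out coverslips
never seen during any fit.
"""

from __future__ import annotations

import json
import logging
import tempfile
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from sevenup.exceptions import (
    CorruptBundleError,
    DimensionMismatchError,
    MissingMarkerError,
)
from sevenup.io_formats import NORM_PREFIX, CellTable, PanelManifest

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ImputerHyperparams:
    learning_rate: float = 0.1
    n_estimators: int = 500
    max_depth: int = 3
    colsample_bytree: float = 0.7
    objective: str = "reg:squarederror"


@dataclass
class ImputationBundle:
    """Panel definition + fitted regressors + feature layout."""

    manifest: PanelManifest
    regressors: dict[str, xgb.XGBRegressor]
    feature_spec: tuple[str, ...]
    hyperparams: ImputerHyperparams
    seed: int
    normalization_stats: dict | None = None
    featurizer: object | None = None  # FeaturizerEnsemble; stored in the archive

    @property
    def n_features(self) -> int:
        return len(self.feature_spec)

    # -- persistence: zip archive with a format-version field ---------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            meta = {
                "format_version": BUNDLE_FORMAT_VERSION,
                "all_markers": list(self.manifest.all_markers),
                "measured_markers": list(self.manifest.measured_markers),
                "feature_spec": list(self.feature_spec),
                "hyperparams": asdict(self.hyperparams),
                "seed": self.seed,
                "normalization_stats": self.normalization_stats,
            }
            zf.writestr("meta.json", json.dumps(meta))
            with tempfile.TemporaryDirectory() as tmp:
                for marker, model in self.regressors.items():
                    f = Path(tmp) / f"{marker}.ubj"
                    model.get_booster().save_model(str(f))
                    zf.write(f, f"models/{marker}.ubj")
                if self.featurizer is not None:
                    f = Path(tmp) / "featurizer.npz"
                    self.featurizer.save(f)
                    zf.write(f, "featurizer.npz")

    @classmethod
    def load(cls, path: str | Path) -> "ImputationBundle":
        path = Path(path)
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("meta.json"))
                if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
                    raise CorruptBundleError(
                        f"bundle format version {meta.get('format_version')} "
                        f"!= {BUNDLE_FORMAT_VERSION}"
                    )
                manifest = PanelManifest(
                    all_markers=tuple(meta["all_markers"]),
                    measured_markers=tuple(meta["measured_markers"]),
                )
                regressors: dict[str, xgb.XGBRegressor] = {}
                with tempfile.TemporaryDirectory() as tmp:
                    for marker in manifest.imputed_markers:
                        name = f"models/{marker}.ubj"
                        if name not in zf.namelist():
                            raise CorruptBundleError(f"bundle missing {name}")
                        f = Path(tmp) / f"{marker}.ubj"
                        f.write_bytes(zf.read(name))
                        model = xgb.XGBRegressor()
                        model.load_model(str(f))
                        regressors[marker] = model
                    featurizer = None
                    if "featurizer.npz" in zf.namelist():
                        from sevenup.featurizer import FeaturizerEnsemble

                        f = Path(tmp) / "featurizer.npz"
                        f.write_bytes(zf.read("featurizer.npz"))
                        featurizer = FeaturizerEnsemble.load(f)
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
            raise CorruptBundleError(f"unreadable bundle {path}: {exc}") from exc
        return cls(
            manifest=manifest,
            regressors=regressors,
            feature_spec=tuple(meta["feature_spec"]),
            hyperparams=ImputerHyperparams(**meta["hyperparams"]),
            seed=meta["seed"],
            normalization_stats=meta.get("normalization_stats"),
            featurizer=featurizer,
        )


def _feature_matrix(
    table: CellTable,
    manifest: PanelManifest,
    features: np.ndarray | None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    x = table.norm_matrix(manifest.measured_markers)
    spec = tuple(NORM_PREFIX + m for m in manifest.measured_markers)
    if features is not None:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[0] != len(table):
            raise DimensionMismatchError(
                f"features shape {features.shape} not row-aligned with "
                f"{len(table)} cells"
            )
        x = np.hstack([x, features])
        spec = spec + tuple(f"proba_{i}" for i in range(features.shape[1]))
    return x, spec


def fit_imputer(
    table: CellTable,
    manifest: PanelManifest,
    features: np.ndarray | None = None,
    seed: int = 0,
    hyperparams: ImputerHyperparams | None = None,
) -> ImputationBundle:
    """Fit one regressor per imputed marker on [measured ‖ morphology-proba].

    ``features = None`` fits the expression-only ablation model.  Training
    requires normalized expressions for the *full* panel (the targets).
    """
    hyperparams = hyperparams or ImputerHyperparams()
    x, spec = _feature_matrix(table, manifest, features)
    regressors: dict[str, xgb.XGBRegressor] = {}
    for marker in manifest.imputed_markers:
        col = NORM_PREFIX + marker
        if col not in table.df.columns:
            raise MissingMarkerError(f"training table missing {col}")
        model = xgb.XGBRegressor(
            **asdict(hyperparams),
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        model.fit(x, table.df[col].to_numpy(dtype=float))
        regressors[marker] = model
    return ImputationBundle(
        manifest=manifest,
        regressors=regressors,
        feature_spec=spec,
        hyperparams=hyperparams,
        seed=seed,
    )


def impute(
    bundle: ImputationBundle,
    table: CellTable,
    features: np.ndarray | None = None,
) -> CellTable:
    """Fill ``norm_<marker>`` for every imputed marker; measured columns untouched.

    Deterministic; a zero-row table yields a zero-row output with the full
    schema.
    """
    x, spec = _feature_matrix(table, bundle.manifest, features)
    if spec != bundle.feature_spec:
        raise DimensionMismatchError(
            f"feature spec mismatch: bundle expects {bundle.feature_spec}, "
            f"got {spec}"
        )
    df = table.df.copy()
    for marker in bundle.manifest.imputed_markers:
        col = NORM_PREFIX + marker
        if len(df) == 0:
            df[col] = pd.Series(dtype=float)
        else:
            df[col] = bundle.regressors[marker].predict(x)
    return CellTable(df)


def split_by_coverslip(
    coverslips: np.ndarray | pd.Series,
    assignment: dict[str, list[str]] | str = "auto",
) -> dict[str, np.ndarray]:
    """Row masks for disjoint train/val/test coverslip groups.

    ``assignment='auto'``: the largest coverslip group goes to train, the
    next to validation, the next (plus any remainder) to test; with fewer
    than three coverslips the later splits reuse the last available group.
    An explicit ``{'train': [...], 'val': [...], 'test': [...]}`` mapping
    must cover disjoint, existing coverslips.
    """
    coverslips = pd.Series(np.asarray(coverslips, dtype=object))
    if assignment == "auto":
        sizes = coverslips.value_counts()
        ordered = list(sizes.index)
        train_ids = [ordered[0]]
        val_ids = [ordered[1]] if len(ordered) > 1 else train_ids
        test_ids = ordered[2:] if len(ordered) > 2 else val_ids
        assignment = {"train": train_ids, "val": val_ids, "test": list(test_ids)}
    else:
        seen: set[str] = set()
        for part, ids in assignment.items():
            overlap = seen & set(ids)
            if overlap:
                raise DimensionMismatchError(
                    f"split groups overlap on coverslips {sorted(overlap)}"
                )
            seen |= set(ids)
        present = set(coverslips.unique())
        missing = set().union(*assignment.values()) - present
        if missing:
            raise DimensionMismatchError(f"unknown coverslips in split: {sorted(missing)}")
    return {
        part: coverslips.isin(ids).to_numpy()
        for part, ids in assignment.items()
    }
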