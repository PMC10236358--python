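"""End-to-end orchestration: quantify → patches → featurize → impute → type → evaluate.

One :class:`RunConfig` drives a full run with coverslip-grouped splitting,
a single master seed (per-stage seeds are fixed offsets from it), and a
JSON-serializable report carrying provenance, per-stage timing, counts and
all evaluation metrics.  The ablation toggles reproduce the three study
comparisons: ``use_morphology=False`` (expression-only imputation),
``use_context_channels=False`` (cell-only patches), and
``single_coverslip_train=True`` (train on one coverslip only).

No stage reads test-coverslip data during any fit: the featurizer trains
on the train coverslip and validates on the validation coverslip; the
imputer fits on train rows; the typing model's clustered reference is
subsampled from train+validation rows only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from sevenup import __version__, celltype, impute as impute_mod, metrics, synthetic
from sevenup.exceptions import SevenUpError
from sevenup.featurizer import FeaturizerConfig, morphology_features, train_featurizer
from sevenup.io_formats import (
    CellTable,
    PanelManifest,
    write_cell_table,
)
from sevenup.panel_select import SelectorConfig, concrete_select, greedy_select
from sevenup.patches import PatchConfig, extract_patches, pool_patches
from sevenup.quantify import dilate_mask, mean_expression, normalize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed for one end-to-end run on synthetic tissue."""

    recipe: synthetic.TissueRecipe
    coverslip_offsets: tuple[float, ...] = (0.0, 0.3, 0.6)
    measured_markers: tuple[str, ...] | int | None = None  # names, or P for auto-select
    panel_method: str = "concrete"  # concrete | greedy
    split: str | dict = "auto"
    use_morphology: bool = True
    use_context_channels: bool = True
    single_coverslip_train: bool = False
    dilate_iterations: int = 9
    featurizer: dict = field(default_factory=dict)  # FeaturizerConfig overrides
    imputer: dict = field(default_factory=dict)  # ImputerHyperparams overrides
    featurizer_max_cells: int = 400  # cap per split for featurizer training
    feature_batch: int = 256  # cells per patch-extraction chunk at inference
    patch_size_px: int = metrics.DEFAULT_PATCH_SIZE
    adjacency_k: int = metrics.ADJACENCY_K
    typing_n_ref: int = celltype.REFERENCE_SIZE
    typing_k: int = celltype.K_CLASSIFY
    cluster_resolution: float = 1.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Default study recipes
# ---------------------------------------------------------------------------


def default_recipe(n_cells: int = 700, seed: int = 0) -> synthetic.TissueRecipe:
    """Four-type tissue with strong measured↔imputed co-expression.

    Measured markers are a pan-immune/epithelial/stromal/proliferation
    quartet; the four imputed markers are noisy linear combinations of
    them (the co-expression structure that makes a small panel
    predictive).  ``n_cells`` is per coverslip.
    """
    measured = ("CD45", "PanCK", "VIM", "KI67")
    imputed = ("CD3", "CD20", "CD68", "SMA")
    mixing = synthetic.MixingSpec(
        inputs=measured,
        outputs=imputed,
        weights=np.array(
            [
                [0.8, 0.0, 0.0, 0.1],  # CD3 tracks CD45
                [0.5, 0.0, 0.0, 0.3],  # CD20
                [0.4, 0.0, 0.3, 0.0],  # CD68
                [0.0, 0.0, 0.9, 0.0],  # SMA tracks VIM
            ]
        ),
        bias=0.2,
        noise_sd=0.15,
    )
    types = (
        synthetic.CellTypeSpec(
            name="tcell", prevalence=0.30, shape="disk", radius=3.5,
            mean_expression={"CD45": 6.0, "PanCK": 0.5, "VIM": 1.0, "KI67": 1.0},
            expression_sd=0.5,
        ),
        synthetic.CellTypeSpec(
            name="tumor", prevalence=0.30, shape="large-disk", radius=6.0,
            mean_expression={"CD45": 0.5, "PanCK": 7.0, "VIM": 1.0, "KI67": 4.0},
            expression_sd=0.5,
        ),
        synthetic.CellTypeSpec(
            name="stromal", prevalence=0.25, shape="ellipse", radius=4.0,
            eccentricity=(0.85, 0.95),
            mean_expression={"CD45": 0.5, "PanCK": 0.5, "VIM": 6.0, "KI67": 1.0},
            expression_sd=0.5,
        ),
        synthetic.CellTypeSpec(
            name="macrophage", prevalence=0.15, shape="disk", radius=5.0,
            mean_expression={"CD45": 4.0, "PanCK": 0.5, "VIM": 3.0, "KI67": 2.0},
            expression_sd=0.5,
        ),
    )
    return synthetic.TissueRecipe(
        markers=measured + imputed,
        n_cells=n_cells,
        image_size=(600, 600),
        cell_types=types,
        mixing=mixing,
        noise_sd=0.2,
        niche_strength=0.6,
        niche_scale=40.0,
        seed=seed,
    )


def ablation_recipe(n_cells: int = 400, seed: int = 0) -> synthetic.TissueRecipe:
    """Recipe where morphology and neighborhood context are each strictly
    informative for some target marker.

    Three focal types share identical measured means: ``elong`` differs
    only by shape (driving the eccentricity marker ``TSHAPE``), and
    ``roundA``/``roundB`` differ only by which bright beacon type they
    co-locate with (driving ``TNICHE_A``/``TNICHE_B``).  Expression-only imputation of
    both targets has Bayes PCC ≈ 0; the cell-only patch recovers TSHAPE
    but not TNICHE; full patches recover both.  ``n_cells`` per coverslip.
    """
    measured = ("M1", "M2")
    base = {"M1": 2.0, "M2": 2.0}
    types = (
        synthetic.CellTypeSpec(
            name="roundA", prevalence=0.21, shape="disk", radius=4.0,
            mean_expression={**base, "TNICHE_A": 6.0, "TNICHE_B": 1.0},
            expression_sd=0.3, niche_group="GA",
        ),
        synthetic.CellTypeSpec(
            name="roundB", prevalence=0.21, shape="disk", radius=4.0,
            mean_expression={**base, "TNICHE_A": 1.0, "TNICHE_B": 6.0},
            expression_sd=0.3, niche_group="GB",
        ),
        # one cell type, present in both niche flavors, so neighborhood
        # context carries no information about it and shape is the only
        # route to TSHAPE
        synthetic.CellTypeSpec(
            name="elong", prevalence=0.10, shape="ellipse", radius=5.0,
            eccentricity=(0.93, 0.97),
            mean_expression={**base, "TNICHE_A": 1.0, "TNICHE_B": 1.0},
            expression_sd=0.3, niche_group="GA",
        ),
        synthetic.CellTypeSpec(
            name="elong", prevalence=0.10, shape="ellipse", radius=5.0,
            eccentricity=(0.93, 0.97),
            mean_expression={**base, "TNICHE_A": 1.0, "TNICHE_B": 1.0},
            expression_sd=0.3, niche_group="GB",
        ),
        synthetic.CellTypeSpec(
            name="beaconX", prevalence=0.19, shape="disk", radius=5.0,
            mean_expression={"M1": 8.0, "M2": 1.0, "TNICHE_A": 1.0, "TNICHE_B": 1.0},
            expression_sd=0.3, niche_group="GA",
        ),
        synthetic.CellTypeSpec(
            name="beaconY", prevalence=0.19, shape="disk", radius=5.0,
            mean_expression={"M1": 1.0, "M2": 8.0, "TNICHE_A": 1.0, "TNICHE_B": 1.0},
            expression_sd=0.3, niche_group="GB",
        ),
    )
    recipe = synthetic.TissueRecipe(
        markers=measured + ("TNICHE_A", "TNICHE_B", "TSHAPE"),
        n_cells=n_cells,
        image_size=(820, 820),
        cell_types=types,
        noise_sd=0.1,
        niche_strength=0.97,
        niche_scale=40.0,
        seed=seed,
    )
    return synthetic.with_shape_marker(recipe, "TSHAPE", low=1.0, high=6.0)


def benchmark_config(seed: int = 0, **overrides) -> RunConfig:
    """Canonical end-to-end benchmark: ~2,100 cells over three coverslips,
    four types, strong co-expression; small-backbone featurizer settings."""
    base = dict(
        recipe=default_recipe(n_cells=700, seed=seed),
        coverslip_offsets=(0.0, 0.3, 0.6),
        measured_markers=("CD45", "PanCK", "VIM", "KI67"),
        featurizer=dict(
            n_members=2, width=8, input_size=32, batch_size=64,
            learning_rate=1e-2, eval_every=50, max_steps=450,
            plateau_evals=5, stop_evals=10,
        ),
        featurizer_max_cells=350,
        seed=seed,
    )
    base.update(overrides)
    return RunConfig(**base)


def ablation_config(
    seed: int = 0,
    use_morphology: bool = True,
    use_context_channels: bool = True,
    **overrides,
) -> RunConfig:
    """Canonical morphology/context ablation on the shape+niche recipe."""
    base = dict(
        recipe=ablation_recipe(n_cells=450, seed=seed),
        coverslip_offsets=(0.0, 0.2, 0.4),
        measured_markers=("M1", "M2"),
        use_morphology=use_morphology,
        use_context_channels=use_context_channels,
        featurizer=dict(
            n_members=2, width=8, input_size=32, batch_size=64,
            learning_rate=1e-2, eval_every=50, max_steps=1400,
            plateau_evals=5, stop_evals=16,
        ),
        featurizer_max_cells=450,
        seed=seed,
    )
    base.update(overrides)
    return RunConfig(**base)


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


class _StageTimer:
    def __init__(self) -> None:
        self.timing: dict[str, float] = {}
        self.completed: list[str] = []

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise SevenUpError(
                f"stage {name!r} failed after completing {self.completed}: {exc}"
            ) from exc
        self.timing[name] = round(time.perf_counter() - t0, 3)
        self.completed.append(name)
        logger.info("stage %s done in %.2fs", name, self.timing[name])
        return out


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the run report (JSON-serializable).

    The report is bit-identical across repeat runs with the same config and
    seed, except for the ``timing`` section.
    """
    timer = _StageTimer()
    seed = config.seed

    # -- simulate ----------------------------------------------------------
    samples, truth = timer.run(
        "simulate",
        synthetic.generate_coverslips,
        config.recipe,
        list(config.coverslip_offsets),
        seed,
    )

    # -- quantify ----------------------------------------------------------
    def _quantify() -> CellTable:
        tables = []
        for i, (stack, mask) in enumerate(samples):
            dilated = dilate_mask(mask, config.dilate_iterations, seed=seed + 100 + i)
            tables.append(mean_expression(stack, dilated))
        table, _stats = normalize(CellTable.concat(tables))
        # carry generative truth (types, eccentricity) along for evaluation
        df = table.df.merge(
            truth.df[["sample_id", "cell_label", "cell_type", "eccentricity"]],
            on=["sample_id", "cell_label"],
            how="left",
        )
        return CellTable(df)

    table = timer.run("quantify", _quantify)

    # -- split -------------------------------------------------------------
    masks = impute_mod.split_by_coverslip(
        table.df["coverslip_id"].to_numpy(), config.split
    )
    if config.single_coverslip_train:
        train_slips = table.df.loc[masks["train"], "coverslip_id"]
        keep = train_slips.value_counts().index[0]
        masks["train"] = masks["train"] & (table.df["coverslip_id"] == keep).to_numpy()

    # -- panel -------------------------------------------------------------
    def _panel() -> PanelManifest:
        all_markers = tuple(config.recipe.markers)
        spec = config.measured_markers
        if isinstance(spec, (tuple, list)):
            return PanelManifest(all_markers=all_markers, measured_markers=tuple(spec))
        if isinstance(spec, int):
            x_train = table.subset(masks["train"]).norm_matrix(all_markers)
            if config.panel_method == "concrete":
                result = concrete_select(
                    x_train, list(all_markers), spec,
                    config=SelectorConfig(), seed=seed + 200,
                )
            else:
                result = greedy_select(x_train, list(all_markers), spec)
            return PanelManifest(
                all_markers=all_markers, measured_markers=result.selected_markers
            )
        raise SevenUpError("measured_markers must be a list of names or an int P")

    manifest = timer.run("panel", _panel)

    # -- featurizer + morphology features ----------------------------------
    features = None
    featurizer_report = None
    if config.use_morphology:
        patch_cfg = PatchConfig(use_context=config.use_context_channels)
        fz_cfg = FeaturizerConfig(**{"seed": seed + 300, **config.featurizer})

        def _featurize():
            rng = np.random.default_rng(seed + 400)
            df = table.df
            # extract every cell's patches once, pooled straight to the
            # backbone's input size (full 224² tensors are never all in
            # memory at once)
            pooled = np.empty(
                (len(df), 3 * len(manifest.measured_markers),
                 fz_cfg.input_size, fz_cfg.input_size),
                dtype=np.float32,
            )
            for start in range(0, len(df), config.feature_batch):
                rows = np.arange(start, min(start + config.feature_batch, len(df)))
                chunk = _patches_for_rows(samples, table, rows, manifest, patch_cfg)
                pooled[rows] = pool_patches(chunk, fz_cfg.input_size)
            train_idx = _cap(np.flatnonzero(masks["train"]), config.featurizer_max_cells, rng)
            val_idx = _cap(np.flatnonzero(masks["val"]), config.featurizer_max_cells, rng)
            ensemble = train_featurizer(
                pooled[train_idx],
                df["cell_type"].to_numpy()[train_idx],
                pooled[val_idx],
                df["cell_type"].to_numpy()[val_idx],
                fz_cfg,
            )
            feats = morphology_features(ensemble, pooled)
            report = {
                "class_names": list(ensemble.class_names),
                "best_val_f1": [
                    max(f for _, f in log) if log else None
                    for log in ensemble.training_logs
                ],
            }
            return feats, report, ensemble

        features, featurizer_report, ensemble = timer.run("featurize", _featurize)
    else:
        ensemble = None

    # -- impute ------------------------------------------------------------
    def _impute():
        train_table = table.subset(masks["train"])
        train_feats = features[masks["train"]] if features is not None else None
        hp = impute_mod.ImputerHyperparams(**config.imputer)
        bundle = impute_mod.fit_imputer(
            train_table, manifest, train_feats, seed=seed + 500, hyperparams=hp
        )
        bundle.featurizer = ensemble  # one archive carries the whole model
        imputed = impute_mod.impute(bundle, _strip_imputed(table, manifest), features)
        return bundle, imputed

    bundle, imputed_table = timer.run("impute", _impute)

    # -- typing ------------------------------------------------------------
    def _typing():
        fit_mask = masks["train"] | masks["val"]
        fit_table = table.subset(fit_mask)
        rng = np.random.default_rng(seed + 600)
        ref_idx = _cap(np.arange(len(fit_table)), config.typing_n_ref, rng)
        ref_table = fit_table.subset(np.isin(np.arange(len(fit_table)), ref_idx))
        clusters = celltype.cluster_reference(
            ref_table, markers=list(manifest.all_markers),
            resolution=config.cluster_resolution, seed=seed + 700,
        )
        annotation = celltype.annotate_clusters_by_majority(
            clusters, ref_table.df["cell_type"].to_numpy()
        )
        model = celltype.fit_typing_model(
            ref_table, clusters, annotation,
            markers=list(manifest.all_markers),
            n_ref=config.typing_n_ref, k_classify=config.typing_k,
            seed=seed + 800,
        )
        knn_truth = celltype.predict_types(model, table)
        predicted = celltype.predict_types_with_substitution(
            model, table, list(manifest.measured_markers), imputed_table
        )
        return model, knn_truth, predicted

    _model, knn_truth_types, predicted_types = timer.run("type", _typing)

    # -- evaluate (test split only) -----------------------------------------
    def _evaluate() -> dict:
        test = masks["test"]
        df = table.df.loc[test]
        grid = metrics.PatchGrid.from_centroids(
            df["centroid_x"].to_numpy(), df["centroid_y"].to_numpy(),
            df["sample_id"].to_numpy(), config.patch_size_px,
        )
        truth_m = table.subset(test).norm_matrix(manifest.imputed_markers)
        pred_m = imputed_table.subset(test).norm_matrix(manifest.imputed_markers)
        pcc = {
            m: metrics.patchwise_pcc(truth_m[:, j], pred_m[:, j], grid)
            for j, m in enumerate(manifest.imputed_markers)
        }
        gen_truth = df["cell_type"].to_numpy()
        knn_truth = knn_truth_types[test]
        pred = predicted_types[test]
        per_type_f1, weighted_f1 = metrics.patchwise_f1(knn_truth, pred, grid)
        _, weighted_f1_generative = metrics.patchwise_f1(gen_truth, pred, grid)
        type_order = sorted(set(gen_truth) | set(pred))
        adj_true = metrics.adjacency_matrix(
            df["centroid_x"].to_numpy(), df["centroid_y"].to_numpy(),
            knn_truth, type_order, k=config.adjacency_k,
        )
        adj_pred = metrics.adjacency_matrix(
            df["centroid_x"].to_numpy(), df["centroid_y"].to_numpy(),
            pred, type_order, k=config.adjacency_k,
        )
        return {
            "patchwise_pcc": pcc,
            "mean_patchwise_pcc": float(np.mean(list(pcc.values()))),
            "per_type_patchwise_f1": per_type_f1,
            "weighted_patchwise_f1": weighted_f1,
            "weighted_patchwise_f1_vs_generative_truth": weighted_f1_generative,
            "adjacency_rmsd": metrics.adjacency_rmsd(adj_true, adj_pred),
            "patch_size_px": config.patch_size_px,
            "n_test_patches": grid.n_patches,
        }

    evaluation = timer.run("evaluate", _evaluate)

    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": seed,
        },
        "counts": {
            "n_cells": len(table),
            "n_train": int(masks["train"].sum()),
            "n_val": int(masks["val"].sum()),
            "n_test": int(masks["test"].sum()),
        },
        "panel": {
            "measured": list(manifest.measured_markers),
            "imputed": list(manifest.imputed_markers),
        },
        "toggles": {
            "use_morphology": config.use_morphology,
            "use_context_channels": config.use_context_channels,
            "single_coverslip_train": config.single_coverslip_train,
        },
        "featurizer": featurizer_report,
        "metrics": evaluation,
        "timing": timer.timing,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cell_table(imputed_table, out_dir / "imputed.csv")
        manifest.to_yaml(out_dir / "manifest.yaml")
        bundle.save(out_dir / "bundle.zip")
        (out_dir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return _jsonable(report)


def _cap(idx: np.ndarray, limit: int, rng: np.random.Generator) -> np.ndarray:
    if len(idx) <= limit:
        return idx
    return np.sort(rng.choice(idx, size=limit, replace=False))


def _patches_for_rows(samples, table: CellTable, rows: np.ndarray,
                      manifest: PanelManifest, patch_cfg: PatchConfig) -> np.ndarray:
    """Extract patch tensors for arbitrary table rows, grouped by sample."""
    df = table.df
    depth = 3 * len(manifest.measured_markers)
    out = np.zeros((len(rows), depth, patch_cfg.patch_size, patch_cfg.patch_size),
                   dtype=np.float32)
    by_sample: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sample_ids = df["sample_id"].to_numpy()
    labels = df["cell_label"].to_numpy()
    for pos, row in enumerate(rows):
        by_sample.setdefault(sample_ids[row], ([], []))  # type: ignore[arg-type]
        by_sample[sample_ids[row]][0].append(pos)
        by_sample[sample_ids[row]][1].append(labels[row])
    stacks = {stack.sample_id: (stack, mask) for stack, mask in samples}
    for sid, (positions, labs) in by_sample.items():
        stack, mask = stacks[sid]
        patches = extract_patches(
            stack, mask, labs, manifest.measured_markers, patch_cfg
        )
        out[np.array(positions)] = patches
    return out


def _strip_imputed(table: CellTable, manifest: PanelManifest) -> CellTable:
    """A copy of the table without the imputed markers' normalized columns
    (what a 7-plex acquisition would actually provide)."""
    drop = [f"norm_{m}" for m in manifest.imputed_markers
            if f"norm_{m}" in table.df.columns]
    return CellTable(table.df.drop(columns=drop))
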