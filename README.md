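# sevenup

Impute a full multiplexed-immunofluorescence biomarker panel from a
measured 7-plex panel plus learned cell-morphology features.

Highly multiplexed imaging (CODEX / PhenoCycler) measures 40+ protein
markers per tissue section but is slow and expensive; clinical mIF
workflows measure at most ~7. `sevenup` is for computational-pathology
and spatial-biology researchers who want CODEX-like per-cell panels from
a small measured panel: it selects the most reconstructive markers,
quantifies per-cell expression from images, learns morphology features
with a convolutional cell-type classifier ensemble, imputes every
unmeasured marker with gradient-boosted trees, derives cell types from
the completed panel, and evaluates fidelity with patchwise metrics.

## Method

For a cell with measured normalized expressions
x ∈ ℝᴾ (P = 7 in the canonical setting) and a patch tensor
T ∈ [0,1]²²⁴ˣ²²⁴ˣ³ᴾ (per measured marker: the masked cell at 3×, a 1×
neighborhood crop, and a 0.5× neighborhood crop), the pipeline computes

- **morphology features** m = mean over an ensemble of 5 CNN classifiers
  of softmax class probabilities p(type | T);
- **imputed expressions** ŷⱼ = fⱼ([x ‖ m]) with one gradient-boosted
  regressor fⱼ per unmeasured marker j (squared error, learning rate
  0.1, 500 estimators, depth 3, column subsampling 0.7);
- **cell types** by majority-vote kNN (k = 30) in the top-20-PC space of
  the full panel, with the imputed values substituted for the unmeasured
  markers against a 10,000-cell labeled reference.

Expressions come from segmentation masks stochastically dilated 9 times
(a background pixel joins a neighboring cell with probability
labeled-neighbors/8) and are normalized per sample as
z = zscore(arcsinh(x / (5·q₀.₂(x)))). The measured panel itself can be
chosen by a concrete selector (temperature-annealed relaxed one-hot
units + MLP decoder) or a greedy ridge-decoder baseline. Evaluation is
patchwise: per-marker Pearson correlation of patch-mean expressions,
per-type patch-presence F1 (weighted by true support), and the RMSD
between spatial cell-type adjacency matrices. See `docs/methods.md`
for assumptions, defaults, and limitations.

## Worked example

Everything runs on synthetic tissue with known ground truth — no data
files needed. A small end-to-end run (three coverslips × 260 cells,
four cell types, strongly co-expressed markers, expression-only
imputation):

```python
from sevenup.pipeline import RunConfig, default_recipe, run

config = RunConfig(
    recipe=default_recipe(n_cells=260, seed=0),
    measured_markers=("CD45", "PanCK", "VIM", "KI67"),
    use_morphology=False,
    seed=0,
)
report = run(config)
print(report["metrics"])
```

prints (abridged):

```
patchwise_pcc: {CD3: 0.958, CD20: 0.937, CD68: 0.957, SMA: 0.985}
mean_patchwise_pcc: 0.959
weighted_patchwise_f1: 1.0
adjacency_rmsd: 0.0
```

Reading: the four unmeasured markers are recovered with patch-level
correlations of 0.94–0.99 from the measured four (they are noisy linear
combinations by construction), the cell types derived from the imputed
panel match the ground-truth typing in every 128 px patch of the
held-out coverslip, and the spatial adjacency structure of the predicted
type map is identical to the truth's.

Panel selection on a 12-marker panel whose last five markers are linear
combinations of the first seven:

```python
from sevenup.panel_select import greedy_select
from sevenup.synthetic import linear_panel_matrix

x, manifest = linear_panel_matrix(n_cells=800, noise_sd=0.05, seed=0)
x = (x - x.mean(0)) / x.std(0)
result = greedy_select(x, list(manifest.all_markers), 7)
print(result.selected_markers, result.reconstruction_mse)
```

```
('M8', 'M9', 'M11', 'M10', 'M12', 'M5', 'M1') 0.00088
```

— any subset spanning the 7-dimensional signal space reconstructs the
panel essentially perfectly; the reported MSE is against all 12 markers.

The morphology story is exercised by `sevenup.pipeline.ablation_config`:
on tissue where an elongated type and two niche-defined round types share
identical measured expressions, the expression-only imputer reaches a
mean patchwise PCC of ~0.2–0.4, adding morphology features lifts it to
~0.8, and zeroing the context channels drops it to ~0.6 — morphology and
neighborhood context each carry real, separable signal.

A CLI mirrors the stages (`sevenup quantify`, `sevenup select-panel`,
`sevenup impute`, `sevenup evaluate`, `sevenup run`); the Python API is
the primary surface.

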