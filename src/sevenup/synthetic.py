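"""Synthetic labeled tissue with known ground truth.

Every downstream stage (quantification, patch extraction, featurizer,
panel selection, imputation, typing, metrics) is exercised against samples
generated here, where the true cell types, expression means, morphologies
and spatial niches are known by construction.

What is emulated
----------------
- labeled cell masks of varied shape: round disks, elongated ellipses,
  and large disks, rasterized without overlap (dart-throwing placement);
- type-conditional marker co-expression: each type has a mean expression
  vector; optionally a mixing matrix makes "imputable" markers exact (or
  noisy) linear functions of the measured ones;
- a shape-coupled marker whose value depends only on cell eccentricity —
  the construction that makes morphology strictly informative and
  expression-only imputation uninformative;
- spatial niches: cells of the same niche group aggregate via a Pólya-urn
  placement (a new cell joins a uniformly chosen existing group member's
  neighborhood with probability ``niche_strength``);
- per-coverslip batch effects as additive per-marker intensity shifts.

Determinism: the same recipe + seed yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sevenup.exceptions import PackingError, SevenUpError
from sevenup.io_formats import CellTable, MarkerImageStack, PanelManifest, SegmentationMask

PLACEMENT_RETRY_FACTOR = 100  # retry cap = factor * n_cells


@dataclass(frozen=True)
class CellTypeSpec:
    """One synthetic cell type: prevalence, shape family, and expression profile."""

    name: str
    prevalence: float
    mean_expression: Mapping[str, float]
    shape: str = "disk"  # disk | ellipse | large-disk
    radius: float = 4.0  # mean radius in px (equal-area radius for ellipses)
    eccentricity: tuple[float, float] = (0.0, 0.0)
    expression_sd: float = 0.0  # within-type biological sd, per marker
    niche_group: str | None = None  # defaults to own name

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SevenUpError(f"type {self.name}: radius must be positive")
        if self.shape not in ("disk", "ellipse", "large-disk"):
            raise SevenUpError(f"type {self.name}: unknown shape {self.shape!r}")


@dataclass(frozen=True)
class ShapeMarkerSpec:
    """A marker whose per-cell value is a pure function of eccentricity.

    value = low + (high - low) * eccentricity.  By design it carries no
    information recoverable from the measured expression means, so an
    expression-only imputer has Bayes PCC 0 on it while a morphology-aware
    one does not.
    """

    name: str
    low: float = 1.0
    high: float = 6.0


@dataclass(frozen=True)
class MixingSpec:
    """Linear co-expression: output markers = weights @ input markers + bias + noise."""

    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    weights: np.ndarray  # (n_outputs, n_inputs)
    bias: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        if w.shape != (len(self.outputs), len(self.inputs)):
            raise SevenUpError(
                f"mixing weights shape {w.shape} != "
                f"({len(self.outputs)}, {len(self.inputs)})"
            )


@dataclass(frozen=True)
class TissueRecipe:
    """Full description of one synthetic sample."""

    markers: tuple[str, ...]
    n_cells: int
    image_size: tuple[int, int]
    cell_types: tuple[CellTypeSpec, ...]
    mixing: MixingSpec | None = None
    shape_markers: tuple[ShapeMarkerSpec, ...] = ()
    noise_sd: float = 0.0  # additive per-cell per-marker intensity noise
    niche_strength: float = 0.0
    niche_scale: float = 30.0  # sd (px) of the offset from a niche anchor
    radius_jitter: float = 0.1  # relative uniform jitter on cell radius
    coverslip_offsets: Mapping[str, float] = field(default_factory=dict)  # marker -> shift
    sample_id: str = "S0"
    coverslip_id: str = "C0"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "shape_markers", tuple(self.shape_markers))
        prev = np.array([t.prevalence for t in self.cell_types], dtype=float)
        if prev.size == 0 or abs(prev.sum() - 1.0) > 1e-9 or (prev < 0).any():
            raise SevenUpError("type prevalences must be nonnegative and sum to 1")
        if not (0.0 <= self.niche_strength <= 1.0):
            raise SevenUpError("niche_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise SevenUpError("noise_sd must be nonnegative")
        for sm in self.shape_markers:
            if sm.name not in self.markers:
                raise SevenUpError(f"shape marker {sm.name!r} not in marker list")


def with_shape_marker(
    recipe: TissueRecipe, name: str, low: float = 1.0, high: float = 6.0
) -> TissueRecipe:
    """Return a recipe whose marker ``name`` is driven purely by eccentricity.

    Requires at least two shape families so the marker is informative;
    intended for recipes where those families share the same measured-marker
    means, making morphology the only route to the target.
    """
    families = {(t.shape, t.eccentricity) for t in recipe.cell_types}
    if len(families) < 2:
        raise SevenUpError("shape marker needs >= 2 distinct shape families")
    markers = recipe.markers if name in recipe.markers else recipe.markers + (name,)
    return replace(
        recipe,
        markers=markers,
        shape_markers=recipe.shape_markers + (ShapeMarkerSpec(name, low, high),),
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _semi_axes(radius: float, eccentricity: float) -> tuple[float, float]:
    """Equal-area semi-axes for a given eccentricity: a*b = radius^2."""
    q = (1.0 - eccentricity**2) ** 0.25
    return radius / q, radius * q


def rasterize_ellipse(
    center: tuple[float, float], a: float, b: float, theta: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centers fall inside the ellipse."""
    cy, cx = center
    h, w = shape
    r_max = max(a, b)
    y0, y1 = max(0, int(math.floor(cy - r_max))), min(h - 1, int(math.ceil(cy + r_max)))
    x0, x1 = max(0, int(math.floor(cx - r_max))), min(w - 1, int(math.ceil(cx + r_max)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    return yy[inside], xx[inside]


def _place_cells(recipe: TissueRecipe, rng: np.random.Generator, type_ids, radii):
    """Dart-throwing placement with Pólya-urn niche aggregation.

    Returns (centers (n,2) float [row, col]).  Raises PackingError if the
    retry cap (100 * n_cells) is exhausted.
    """
    h, w = recipe.image_size
    n = recipe.n_cells
    groups = [
        recipe.cell_types[t].niche_group or recipe.cell_types[t].name for t in type_ids
    ]
    centers = np.empty((n, 2), dtype=float)
    placed_r = np.empty(n, dtype=float)
    by_group: dict[str, list[int]] = {}
    retries = PLACEMENT_RETRY_FACTOR * n
    margin = radii + 1.0
    for i in range(n):
        ri = radii[i]
        if h - 2 * (ri + 1) <= 0 or w - 2 * (ri + 1) <= 0:
            raise PackingError(f"image {recipe.image_size} too small for radius {ri:.1f}")
        anchors = by_group.get(groups[i], [])
        while True:
            use_niche = anchors and rng.random() < recipe.niche_strength
            if use_niche:
                j = anchors[rng.integers(len(anchors))]
                cand = centers[j] + rng.normal(0.0, recipe.niche_scale, size=2)
                cand[0] = min(max(cand[0], ri + 1), h - ri - 2)
                cand[1] = min(max(cand[1], ri + 1), w - ri - 2)
            else:
                cand = np.array(
                    [
                        rng.uniform(ri + 1, h - ri - 2),
                        rng.uniform(ri + 1, w - ri - 2),
                    ]
                )
            if i == 0:
                break
            d2 = np.sum((centers[:i] - cand) ** 2, axis=1)
            if (d2 > (margin[:i] + ri) ** 2).all():
                break
            retries -= 1
            if retries <= 0:
                raise PackingError(
                    f"could not place {n} cells of the requested sizes in "
                    f"{recipe.image_size} within the retry cap"
                )
        centers[i] = cand
        placed_r[i] = ri
        by_group.setdefault(groups[i], []).append(i)
    return centers


# ---------------------------------------------------------------------------
# Sample generation
# ---------------------------------------------------------------------------


def generate_sample(
    recipe: TissueRecipe, seed: int | None = None
) -> tuple[MarkerImageStack, SegmentationMask, CellTable]:
    """Generate one sample: marker images, labeled mask, and the truth table.

    The returned cell table records, per cell, the true type, eccentricity,
    and the exact intensity painted inside the cell for every marker
    (columns ``raw_<marker>``), so quantification can be validated against
    it exactly in the noiseless limit.
    """
    rng = np.random.default_rng(recipe.seed if seed is None else seed)
    n = recipe.n_cells
    types = recipe.cell_types
    prev = np.array([t.prevalence for t in types])
    type_ids = rng.choice(len(types), size=n, p=prev)

    # per-cell geometry
    radii = np.empty(n)
    eccs = np.empty(n)
    thetas = rng.uniform(0, math.pi, size=n)
    for i, t in enumerate(type_ids):
        spec = types[t]
        jit = 1.0 + rng.uniform(-recipe.radius_jitter, recipe.radius_jitter)
        radii[i] = spec.radius * jit
        lo, hi = spec.eccentricity
        eccs[i] = rng.uniform(lo, hi) if hi > lo else lo
        if spec.shape != "ellipse":
            eccs[i] = 0.0

    centers = _place_cells(recipe, rng, type_ids, radii)

    # per-cell expression values
    shape_by_name = {sm.name: sm for sm in recipe.shape_markers}
    mixed_outputs = set(recipe.mixing.outputs) if recipe.mixing else set()
    values = np.zeros((n, len(recipe.markers)))
    marker_pos = {m: j for j, m in enumerate(recipe.markers)}
    for j, m in enumerate(recipe.markers):
        if m in shape_by_name or m in mixed_outputs:
            continue
        mu = np.array([types[t].mean_expression.get(m, 0.0) for t in type_ids])
        sd = np.array([types[t].expression_sd for t in type_ids])
        values[:, j] = mu + sd * rng.standard_normal(n)
    for sm in recipe.shape_markers:
        values[:, marker_pos[sm.name]] = sm.low + (sm.high - sm.low) * eccs
    if recipe.mixing is not None:
        mix = recipe.mixing
        x_in = values[:, [marker_pos[m] for m in mix.inputs]]
        y = x_in @ mix.weights.T + mix.bias
        if mix.noise_sd > 0:
            y = y + mix.noise_sd * rng.standard_normal(y.shape)
        for k, m in enumerate(mix.outputs):
            values[:, marker_pos[m]] = y[:, k]
    for m, shift in recipe.coverslip_offsets.items():
        if m in marker_pos:
            values[:, marker_pos[m]] += shift
    if recipe.noise_sd > 0:
        values = values + recipe.noise_sd * rng.standard_normal(values.shape)
    values = np.clip(values, 0.0, None)

    # rasterize mask and paint channels
    h, w = recipe.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    images = np.zeros((len(recipe.markers), h, w), dtype=np.float64)
    cent_x = np.empty(n)
    cent_y = np.empty(n)
    for i in range(n):
        a, b = _semi_axes(radii[i], eccs[i])
        ys, xs = rasterize_ellipse(tuple(centers[i]), a, b, thetas[i], (h, w))
        if ys.size == 0:  # sub-pixel cell; keep at least the center pixel
            ys = np.array([int(round(centers[i, 0]))])
            xs = np.array([int(round(centers[i, 1]))])
        labels[ys, xs] = i + 1
        images[:, ys, xs] = values[i][:, None]
        cent_y[i] = ys.mean()
        cent_x[i] = xs.mean()

    stack = MarkerImageStack(
        channels={m: images[j] for j, m in enumerate(recipe.markers)},
        sample_id=recipe.sample_id,
        coverslip_id=recipe.coverslip_id,
    )
    mask = SegmentationMask(labels=labels)
    df = pd.DataFrame(
        {
            "sample_id": recipe.sample_id,
            "cell_label": np.arange(1, n + 1, dtype=np.int64),
            "coverslip_id": recipe.coverslip_id,
            "centroid_x": cent_x,
            "centroid_y": cent_y,
            "cell_type": [types[t].name for t in type_ids],
            "eccentricity": eccs,
        }
    )
    for j, m in enumerate(recipe.markers):
        df[f"raw_{m}"] = values[:, j]
    return stack, mask, CellTable(df)


def generate_coverslips(
    recipe: TissueRecipe,
    coverslip_offsets: Sequence[Mapping[str, float] | float],
    seed: int | None = None,
) -> tuple[list[tuple[MarkerImageStack, SegmentationMask]], CellTable]:
    """Generate one sample per coverslip, with per-coverslip batch shifts.

    ``coverslip_offsets`` gives, per coverslip, either a scalar shift applied
    to all markers or a marker → shift mapping.  Sample ids are S0..Sk and
    coverslip ids C0..Ck; sample k uses seed ``base_seed + k``.
    """
    base = recipe.seed if seed is None else seed
    outputs = []
    tables = []
    for k, off in enumerate(coverslip_offsets):
        if isinstance(off, (int, float)):
            off = {m: float(off) for m in recipe.markers}
        sub = replace(
            recipe,
            sample_id=f"S{k}",
            coverslip_id=f"C{k}",
            coverslip_offsets=dict(off),
            seed=base + k,
        )
        stack, mask, table = generate_sample(sub)
        outputs.append((stack, mask))
        tables.append(table)
    return outputs, CellTable.concat(tables)


# ---------------------------------------------------------------------------
# Matrix-level generators (no images): structured panels for selection and
# imputation studies
# ---------------------------------------------------------------------------


def linear_panel_matrix(
    n_cells: int = 2000,
    n_measured: int = 7,
    n_markers: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, PanelManifest]:
    """Cells × markers matrix where the trailing markers are noiseless (or
    noisy) linear combinations of the leading ``n_measured`` ones.

    The leading block is unit-variance Gaussian; the mixing weights are a
    fixed random full-rank map.  Any marker subset spanning the leading
    block reconstructs the panel with MSE equal to ``noise_sd**2``.
    """
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_cells, n_measured))
    w = rng.normal(0.0, 1.0, size=(n_markers - n_measured, n_measured))
    derived = base @ w.T
    if noise_sd > 0:
        derived = derived + noise_sd * rng.standard_normal(derived.shape)
    x = np.hstack([base, derived])
    names = tuple(f"M{i + 1}" for i in range(n_markers))
    manifest = PanelManifest(all_markers=names, measured_markers=names[:n_measured])
    return x, manifest


def attenuated_targets(
    n_cells: int = 4000,
    n_measured: int = 7,
    signal_sd: float = 1.0,
    noise_sd: float = 0.5,
    n_targets: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Targets that are linear in the measured block plus Gaussian noise.

    Each target is a unit-norm random combination of the measured markers
    scaled to sd ``signal_sd``, plus N(0, noise_sd²).  The best attainable
    held-out PCC is the attenuation factor s/sqrt(s² + σ²); it is returned
    alongside (X, Y).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_cells, n_measured))
    w = rng.standard_normal((n_targets, n_measured))
    w = w / np.linalg.norm(w, axis=1, keepdims=True)
    y = signal_sd * (x @ w.T) + noise_sd * rng.standard_normal((n_cells, n_targets))
    expected_pcc = signal_sd / math.sqrt(signal_sd**2 + noise_sd**2)
    return x, y, expected_pcc
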