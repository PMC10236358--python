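"""Choose the P measured markers that best reconstruct the full panel.

Two methods:

- :func:`concrete_select` — a concrete selector network: P selector units,
  each a temperature-annealed relaxed one-hot distribution over markers,
  feeding a small MLP decoder trained to reconstruct the whole normalized
  expression matrix under MSE.  As the temperature anneals (geometrically,
  10 → 0.01 by default) each unit concentrates on one marker; at the end
  the per-unit argmax defines the selected panel.
- :func:`greedy_select` — forward selection: iteratively add the marker
  that most reduces the full-panel reconstruction MSE of a ridge decoder.

Both report their final reconstruction MSE from a ridge decoder refit on
the hard-selected subset, so the two methods (and an exhaustive search)
are compared on one common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from sevenup import _nn
from sevenup.exceptions import SevenUpError

logger = logging.getLogger(__name__)


@dataclass
class SelectorConfig:
    decoder_hidden: tuple[int, int] = (64, 64)
    epochs: int = 300
    batch_size: int = 256
    learning_rate: float = 1e-2
    t_start: float = 10.0
    t_end: float = 0.01
    max_restarts: int = 5
    ridge_alpha: float = 1e-3


@dataclass
class SelectorResult:
    selected_markers: tuple[str, ...]
    reconstruction_mse: float
    method: str  # concrete | greedy
    temperature_schedule: tuple[float, float, int] | None
    seed: int | None


def subset_mse(x: np.ndarray, subset: list[int], alpha: float = 1e-3) -> float:
    """Full-panel reconstruction MSE of a ridge decoder given a marker subset."""
    if len(subset) == 0:
        return float(np.mean((x - x.mean(axis=0)) ** 2))
    model = Ridge(alpha=alpha)
    model.fit(x[:, subset], x)
    pred = model.predict(x[:, subset])
    return float(np.mean((pred - x) ** 2))


def greedy_select(
    x: np.ndarray,
    marker_names: list[str],
    p: int,
    config: SelectorConfig | None = None,
) -> SelectorResult:
    """Deterministic forward selection under the ridge-decoder MSE."""
    config = config or SelectorConfig()
    _check(x, marker_names, p, allow_zero=True)
    chosen: list[int] = []
    remaining = list(range(x.shape[1]))
    for _ in range(p):
        scores = [subset_mse(x, chosen + [j], config.ridge_alpha) for j in remaining]
        best = remaining[int(np.argmin(scores))]
        chosen.append(best)
        remaining.remove(best)
    return SelectorResult(
        selected_markers=tuple(marker_names[j] for j in chosen),
        reconstruction_mse=subset_mse(x, chosen, config.ridge_alpha),
        method="greedy",
        temperature_schedule=None,
        seed=None,
    )


def concrete_select(
    x: np.ndarray,
    marker_names: list[str],
    p: int,
    config: SelectorConfig | None = None,
    seed: int = 0,
) -> SelectorResult:
    """Concrete-selector panel choice; seed-reproducible.

    If the P units' argmaxes collide, the selector is re-annealed with a
    fresh seed (up to ``max_restarts``); any slots still duplicated are
    filled greedily.  If training degenerates entirely the greedy baseline
    is returned with a warning.
    """
    config = config or SelectorConfig()
    _check(x, marker_names, p, allow_zero=False)
    m = x.shape[1]
    if p == m:
        return SelectorResult(
            selected_markers=tuple(marker_names),
            reconstruction_mse=subset_mse(x, list(range(m)), config.ridge_alpha),
            method="concrete",
            temperature_schedule=(config.t_start, config.t_end, config.epochs),
            seed=seed,
        )
    selected: list[int] | None = None
    for attempt in range(config.max_restarts + 1):
        picks = _train_concrete(x, p, config, seed + attempt)
        if len(set(picks)) == p:
            selected = picks
            break
        logger.info(
            "concrete selector restart %d: duplicate argmaxes %s", attempt + 1, picks
        )
        selected = picks  # keep last; deduplicate below if restarts exhausted
    if selected is None:  # pragma: no cover - defensive
        logger.warning("concrete selector failed to train; falling back to greedy")
        fallback = greedy_select(x, marker_names, p, config)
        return SelectorResult(
            selected_markers=fallback.selected_markers,
            reconstruction_mse=fallback.reconstruction_mse,
            method="concrete",
            temperature_schedule=(config.t_start, config.t_end, config.epochs),
            seed=seed,
        )
    unique = list(dict.fromkeys(selected))
    if len(unique) < p:  # greedy fill for still-duplicated slots
        remaining = [j for j in range(m) if j not in unique]
        while len(unique) < p:
            scores = [subset_mse(x, unique + [j], config.ridge_alpha) for j in remaining]
            best = remaining[int(np.argmin(scores))]
            unique.append(best)
            remaining.remove(best)
    return SelectorResult(
        selected_markers=tuple(marker_names[j] for j in unique),
        reconstruction_mse=subset_mse(x, unique, config.ridge_alpha),
        method="concrete",
        temperature_schedule=(config.t_start, config.t_end, config.epochs),
        seed=seed,
    )


def _train_concrete(x: np.ndarray, p: int, config: SelectorConfig, seed: int) -> list[int]:
    rng = np.random.default_rng(seed)
    n, m = x.shape
    alpha = rng.normal(0.0, 0.01, size=(p, m))  # selector logits
    decoder = _nn.mlp(p, config.decoder_hidden, m, rng)
    opt = _nn.Adam([alpha] + decoder.params(), lr=config.learning_rate)
    ratio = config.t_end / config.t_start
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        temp = config.t_start * ratio**frac  # geometric annealing
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=(p, m))))
            s = _nn.softmax((alpha + gumbel) / temp)  # (p, m) relaxed one-hots
            x_sel = xb @ s.T
            pred = decoder.forward(x_sel, train=True)
            _, dpred = _nn.mse_grad(pred, xb)
            dx_sel = decoder.backward(dpred)
            ds = dx_sel.T @ xb  # (p, m)
            # softmax backward per unit, including the 1/temp factor
            dalpha = s * (ds - np.sum(ds * s, axis=1, keepdims=True)) / temp
            grads = [dalpha] + decoder.grads()
            opt.step(grads)
    return list(np.argmax(alpha, axis=1))


def _check(x: np.ndarray, marker_names: list[str], p: int, allow_zero: bool) -> None:
    if x.ndim != 2 or x.shape[1] != len(marker_names):
        raise SevenUpError("x must be cells × markers aligned with marker_names")
    lower = 0 if allow_zero else 1
    if not (lower <= p <= x.shape[1]):
        raise SevenUpError(f"need {lower} <= P <= n_markers, got P={p}")
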