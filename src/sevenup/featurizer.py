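"""Morphology featurizer: an ensemble of convolutional cell-type classifiers.

The featurizer is trained to classify cell types from the per-cell patch
tensors (cell-only + two context channels per measured marker).  Its
*output probabilities* — averaged over an ensemble of five identically
configured members with different random initializations — are the
morphology feature vector handed to the imputation regressors; using the
probabilities directly works better than the penultimate-layer embedding.

Training protocol: categorical cross-entropy; validation class-weighted F1
computed every ``eval_every`` steps; learning rate decays ×0.2 when the
validation F1 has not improved for ``plateau_evals`` evaluations; training
stops after ``stop_evals`` evaluations without improvement (or at
``max_steps``); the checkpoint with the best validation F1 is kept.  At
production scale those windows are 5,000-step and 75,000-step plateaus
with an initial learning rate of 1e-4.

The backbone here is a small 3-block CNN on area-pooled patches — adequate
for the package's synthetic problem sizes and fully deterministic; the
architecture is config-switched so a larger pretrained residual backbone
can be dropped in where the compute exists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import f1_score

from sevenup import _nn
from sevenup.exceptions import DimensionMismatchError, SevenUpError
from sevenup.patches import pool_patches

logger = logging.getLogger(__name__)


@dataclass
class FeaturizerConfig:
    n_members: int = 5
    backbone: str = "small_cnn"
    width: int = 16  # first conv width of the small backbone
    input_size: int = 32  # patches are area-pooled to this before the CNN
    batch_size: int = 64
    learning_rate: float = 1e-4
    lr_decay: float = 0.2
    standardize: bool = True  # per-channel z-scoring of pooled inputs
    eval_every: int = 1000  # steps between validation evaluations
    plateau_evals: int = 5  # evals without improvement before LR decay
    stop_evals: int = 75  # evals without improvement before stopping
    max_steps: int = 100_000
    min_improvement: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone != "small_cnn":
            raise SevenUpError(
                f"backbone {self.backbone!r} unavailable; only 'small_cnn' ships"
            )


@dataclass
class FeaturizerEnsemble:
    """Trained classifier ensemble; the averaged class-probability vector is
    the morphology feature."""

    members: list[_nn.Sequential]
    class_names: tuple[str, ...]
    input_depth: int
    input_size: int
    width: int
    channel_mean: np.ndarray | None = None  # per-channel standardization,
    channel_sd: np.ndarray | None = None  # computed on the training set
    training_logs: list[list[tuple[int, float]]] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def member_proba(self, member: int, patches: np.ndarray, batch: int = 256) -> np.ndarray:
        x = self._prepare(patches)
        model = self.members[member]
        out = np.empty((x.shape[0], self.n_classes))
        for i in range(0, x.shape[0], batch):
            out[i : i + batch] = _nn.softmax(model.forward(x[i : i + batch], train=False))
        return out

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Mean of the members' probability vectors (the morphology feature)."""
        x = self._prepare(patches)
        acc = np.zeros((x.shape[0], self.n_classes))
        for model in self.members:
            for i in range(0, x.shape[0], 256):
                acc[i : i + 256] += _nn.softmax(model.forward(x[i : i + 256], train=False))
        return acc / len(self.members)

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        if patches.ndim != 4 or patches.shape[1] != self.input_depth:
            raise DimensionMismatchError(
                f"expected (n, {self.input_depth}, S, S) patches, got {patches.shape}"
            )
        if patches.shape[2] != self.input_size:
            patches = pool_patches(patches, self.input_size)
        patches = patches.astype(_nn.DTYPE)
        if self.channel_mean is not None:
            patches = (patches - self.channel_mean) / self.channel_sd
        return patches

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, model in enumerate(self.members):
            for j, p in enumerate(model.params()):
                arrays[f"m{i}_p{j}"] = p
        if self.channel_mean is not None:
            arrays["channel_mean"] = self.channel_mean
            arrays["channel_sd"] = self.channel_sd
        meta = {
            "class_names": list(self.class_names),
            "input_depth": self.input_depth,
            "input_size": self.input_size,
            "width": self.width,
            "n_members": len(self.members),
            "training_logs": self.training_logs,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FeaturizerEnsemble":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        rng = np.random.default_rng(0)  # shapes only; weights overwritten
        members = []
        for i in range(meta["n_members"]):
            model = _nn.small_cnn(
                meta["input_depth"], len(meta["class_names"]), rng,
                input_size=meta["input_size"], width=meta["width"],
            )
            model.load_state([data[f"m{i}_p{j}"] for j in range(len(model.params()))])
            members.append(model)
        return cls(
            members=members,
            class_names=tuple(meta["class_names"]),
            input_depth=meta["input_depth"],
            input_size=meta["input_size"],
            width=meta["width"],
            channel_mean=data["channel_mean"] if "channel_mean" in data else None,
            channel_sd=data["channel_sd"] if "channel_sd" in data else None,
            training_logs=[[tuple(t) for t in log] for log in meta["training_logs"]],
        )


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    class_names = tuple(sorted(set(str(v) for v in labels)))
    lookup = {c: i for i, c in enumerate(class_names)}
    return np.array([lookup[str(v)] for v in labels]), class_names


def train_featurizer(
    patches: np.ndarray,
    labels: np.ndarray,
    val_patches: np.ndarray,
    val_labels: np.ndarray,
    config: FeaturizerConfig | None = None,
) -> FeaturizerEnsemble:
    """Train the ensemble on a coverslip-grouped train/validation split.

    ``patches``: (n, 3P, S, S) in [0, 1]; ``labels``: cell-type strings.
    The caller supplies the split (use :func:`sevenup.impute.split_by_coverslip`
    to hold out whole coverslips).  Member m trains with seed
    ``config.seed + m``; given identical seeds members are identical.
    """
    config = config or FeaturizerConfig()
    if len(patches) != len(labels) or len(val_patches) != len(val_labels):
        raise DimensionMismatchError("patches and labels must be row-aligned")
    if val_patches.shape[0] == 0:
        raise SevenUpError("validation set is empty")
    y_all, class_names = _encode_labels(np.concatenate([labels, val_labels]))
    y = y_all[: len(labels)]
    y_val = y_all[len(labels):]
    if len(set(y.tolist())) < 2 or len(set(y_val.tolist())) < 2:
        raise SevenUpError("need >= 2 classes in both train and validation sets")
    depth = patches.shape[1]
    x = pool_patches(patches, config.input_size).astype(_nn.DTYPE) \
        if patches.shape[2] != config.input_size else patches.astype(_nn.DTYPE)
    x_val = pool_patches(val_patches, config.input_size).astype(_nn.DTYPE) \
        if val_patches.shape[2] != config.input_size else val_patches.astype(_nn.DTYPE)
    channel_mean = channel_sd = None
    if config.standardize:
        channel_mean = x.mean(axis=(0, 2, 3), keepdims=True).astype(_nn.DTYPE)
        channel_sd = (x.std(axis=(0, 2, 3), keepdims=True) + 1e-6).astype(_nn.DTYPE)
        x = (x - channel_mean) / channel_sd
        x_val = (x_val - channel_mean) / channel_sd

    members: list[_nn.Sequential] = []
    logs: list[list[tuple[int, float]]] = []
    for m in range(config.n_members):
        rng = np.random.default_rng(config.seed + m)
        model = _nn.small_cnn(
            depth, len(class_names), rng,
            input_size=config.input_size, width=config.width,
        )
        log = _train_member(model, x, y, x_val, y_val, len(class_names), config, rng)
        members.append(model)
        logs.append(log)
    return FeaturizerEnsemble(
        members=members,
        class_names=class_names,
        input_depth=depth,
        input_size=config.input_size,
        width=config.width,
        channel_mean=channel_mean,
        channel_sd=channel_sd,
        training_logs=logs,
    )


def _val_f1(model: _nn.Sequential, x_val, y_val, n_classes) -> float:
    preds = np.empty(len(x_val), dtype=int)
    for i in range(0, len(x_val), 256):
        preds[i : i + 256] = model.forward(x_val[i : i + 256], train=False).argmax(axis=1)
    return float(f1_score(y_val, preds, average="weighted", zero_division=0))


def _train_member(model, x, y, x_val, y_val, n_classes, config, rng) -> list[tuple[int, float]]:
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    n = len(x)
    order = rng.permutation(n)
    cursor = 0
    best_f1 = -1.0
    best_state = model.state()
    since_improve = 0
    since_decay = 0
    log: list[tuple[int, float]] = []
    for step in range(1, config.max_steps + 1):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size
        logits = model.forward(x[idx], train=True)
        _, dlogits = _nn.cross_entropy_grad(logits, y[idx])
        model.backward(dlogits.astype(_nn.DTYPE))
        opt.step(model.grads())
        if step % config.eval_every == 0 or step == config.max_steps:
            f1 = _val_f1(model, x_val, y_val, n_classes)
            log.append((step, f1))
            if f1 > best_f1 + config.min_improvement:
                best_f1 = f1
                best_state = model.state()
                since_improve = 0
                since_decay = 0
            else:
                since_improve += 1
                since_decay += 1
                if since_decay >= config.plateau_evals:
                    opt.lr *= config.lr_decay
                    since_decay = 0
                if since_improve >= config.stop_evals:
                    break
    model.load_state(best_state)
    return log


def morphology_features(ensemble: FeaturizerEnsemble, patches: np.ndarray) -> np.ndarray:
    """Per-cell morphology feature: the ensemble-mean class-probability vector."""
    return ensemble.predict_proba(patches)
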