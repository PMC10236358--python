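"""Images + masks → the per-cell expression matrix.

Four steps, applied in order:

1. autofluorescence ("blank") background correction — for a marker acquired
   in cycle c of C, subtract the blend (1-w)·blank_first + w·blank_last
   with w = c/(C-1), clipping at 0 (autofluorescence decays over cycles,
   so interpolating between the first- and last-cycle blanks tracks it);
2. stochastic mask dilation — nine synchronous iterations in which each
   background pixel flips to a neighboring cell's label with probability
   (number of 8-connected neighbors carrying that label)/8, recovering the
   membrane/cytoplasm signal around nuclear segmentations;
3. per-cell mean expression over the (dilated) label's pixels;
4. per-sample normalization z = zscore(arcsinh(x / (5·q0.2(x)))) where
   q0.2 is the 20th percentile of the marker's raw means in the sample and
   the z-score uses the sample's mean and population sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from sevenup.exceptions import (
    DegenerateDispersionError,
    DimensionMismatchError,
    SevenUpError,
)
from sevenup.io_formats import (
    NORM_PREFIX,
    RAW_PREFIX,
    CellTable,
    MarkerImageStack,
    SegmentationMask,
)

logger = logging.getLogger(__name__)

ARCSINH_DIVISOR_SCALE = 5.0  # divisor = scale * q0.2(x)
DILATION_ITERATIONS = 9

# 8-connected neighborhood offsets, fixed order (slot index = position here)
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1),           (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def background_correct(stack: MarkerImageStack) -> MarkerImageStack:
    """Subtract the cycle-interpolated blank image from every channel.

    Without blank images this is the identity (with a logged notice).
    """
    if stack.blank_first is None or stack.blank_last is None:
        logger.info(
            "sample %s: no blank images; background correction skipped",
            stack.sample_id,
        )
        return stack
    if stack.n_cycles is None or stack.n_cycles < 1:
        raise SevenUpError("background correction needs n_cycles >= 1")
    corrected: dict[str, np.ndarray] = {}
    for marker, img in stack.channels.items():
        c = stack.cycle_index.get(marker)
        if c is None:
            raise SevenUpError(f"marker {marker!r} has no cycle index")
        w = 0.0 if stack.n_cycles == 1 else c / (stack.n_cycles - 1)
        blend = (1.0 - w) * stack.blank_first + w * stack.blank_last
        corrected[marker] = np.clip(img - blend, 0.0, None)
    return MarkerImageStack(
        channels=corrected,
        microns_per_pixel=stack.microns_per_pixel,
        sample_id=stack.sample_id,
        coverslip_id=stack.coverslip_id,
        cycle_index=dict(stack.cycle_index),
        n_cycles=stack.n_cycles,
    )


def dilate_mask(
    mask: SegmentationMask,
    iterations: int = DILATION_ITERATIONS,
    seed: int = 0,
) -> SegmentationMask:
    """Stochastically dilate cell labels into the background.

    Per iteration (synchronous, evaluated on the iteration-start mask): a
    background pixel with n_L 8-connected neighbors carrying label L flips
    to L with probability n_L/8; labels are mutually exclusive, so the
    total flip probability is (#labeled neighbors)/8 and the landing label
    is chosen proportionally to neighbor counts.  Cell pixels never revert
    and never overwrite each other.
    """
    if iterations < 0:
        raise SevenUpError("iterations must be >= 0")
    rng = np.random.default_rng(seed)
    labels = mask.labels.copy()
    h, w = labels.shape
    for _ in range(iterations):
        padded = np.pad(labels, 1)
        # neighbor labels per slot: (8, H, W)
        nbr = np.stack(
            [padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w] for dy, dx in _NEIGHBOR_OFFSETS]
        )
        background = labels == 0
        n_pos = (nbr > 0).sum(axis=0)
        flip = background & (rng.random((h, w)) * 8.0 < n_pos)
        if not flip.any():
            continue
        # choose a labeled neighbor slot uniformly at random (Gumbel-style
        # argmax over random scores restricted to labeled slots); uniform
        # over slots of label L gives overall probability n_L/8 of landing
        # on L, as required
        scores = rng.random(nbr.shape)
        scores[nbr == 0] = -1.0
        chosen_slot = scores.argmax(axis=0)
        chosen_label = np.take_along_axis(nbr, chosen_slot[None], axis=0)[0]
        labels = np.where(flip, chosen_label, labels)
    return SegmentationMask(labels=labels)


def mean_expression(
    stack: MarkerImageStack, mask: SegmentationMask
) -> CellTable:
    """Per-cell mean of every channel over the cell's (dilated) pixels.

    Centroids are computed from the mask pixels.  Raises if the mask holds
    no cells or is misaligned with the images.
    """
    if mask.labels.shape != stack.shape:
        raise DimensionMismatchError(
            f"mask shape {mask.labels.shape} != image shape {stack.shape}"
        )
    mask.require_cells()
    cell_labels = mask.cell_labels
    cy, cx = zip(*ndimage.center_of_mass(mask.labels > 0, mask.labels, cell_labels))
    df = pd.DataFrame(
        {
            "sample_id": stack.sample_id,
            "cell_label": cell_labels.astype(np.int64),
            "coverslip_id": stack.coverslip_id,
            "centroid_x": np.asarray(cx, dtype=float),
            "centroid_y": np.asarray(cy, dtype=float),
        }
    )
    for marker, img in stack.channels.items():
        means = ndimage.mean(img, labels=mask.labels, index=cell_labels)
        df[RAW_PREFIX + marker] = np.asarray(means, dtype=float)
    return CellTable(df)


@dataclass
class NormalizationStats:
    """Per-(sample, marker) statistics of the arcsinh/z-score transform.

    ``divisor`` is 5·q0.2(x) (or the smallest positive raw value when the
    20th percentile is zero); ``mu``/``sigma`` are the mean and population
    sd of arcsinh(x/divisor) over the sample's cells.  Applying stored
    stats to the sample they came from reproduces its normalized values
    exactly.
    """

    stats: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def put(self, sample: str, marker: str, q20: float, divisor: float, mu: float, sigma: float):
        self.stats[(sample, marker)] = {
            "q20": q20, "divisor": divisor, "mu": mu, "sigma": sigma
        }

    def get(self, sample: str, marker: str) -> dict[str, float]:
        return self.stats[(sample, marker)]

    def apply(self, sample: str, marker: str, x: np.ndarray) -> np.ndarray:
        s = self.get(sample, marker)
        y = np.arcsinh(np.asarray(x, dtype=float) / s["divisor"])
        return (y - s["mu"]) / s["sigma"]


def normalize(
    table: CellTable,
    markers: list[str] | None = None,
    stats: NormalizationStats | None = None,
) -> tuple[CellTable, NormalizationStats]:
    """Add ``norm_<marker>`` columns; returns the table and the stats used.

    Statistics are computed per sample, never pooled across samples.  When
    ``stats`` is given (frozen-stats inference), they are applied instead of
    recomputed.
    """
    markers = list(markers) if markers is not None else list(table.markers)
    df = table.df.copy()
    out_stats = stats if stats is not None else NormalizationStats()
    for sample, idx in df.groupby("sample_id").groups.items():
        if len(idx) < 2:
            raise SevenUpError(f"sample {sample!r}: need >= 2 cells to normalize")
        for marker in markers:
            x = df.loc[idx, RAW_PREFIX + marker].to_numpy(dtype=float)
            if stats is None:
                q20 = float(np.percentile(x, 20))  # linear interpolation
                if q20 > 0:
                    divisor = ARCSINH_DIVISOR_SCALE * q20
                else:
                    positive = x[x > 0]
                    if positive.size == 0:
                        raise DegenerateDispersionError(
                            f"sample {sample!r}, marker {marker!r}: all values zero"
                        )
                    divisor = float(positive.min())
                    logger.info(
                        "sample %s, marker %s: q0.2 = 0; falling back to smallest "
                        "positive raw value %.4g as divisor", sample, marker, divisor,
                    )
                y = np.arcsinh(x / divisor)
                mu = float(y.mean())
                sigma = float(y.std())  # population sd
                if sigma <= 1e-12 * max(1.0, abs(mu)):
                    raise DegenerateDispersionError(
                        f"sample {sample!r}, marker {marker!r}: zero dispersion"
                    )
                out_stats.put(str(sample), marker, q20, divisor, mu, sigma)
                df.loc[idx, NORM_PREFIX + marker] = (y - mu) / sigma
            else:
                df.loc[idx, NORM_PREFIX + marker] = out_stats.apply(
                    str(sample), marker, x
                )
    return CellTable(df), out_stats


def quantify_sample(
    stack: MarkerImageStack,
    mask: SegmentationMask,
    dilate_iterations: int = DILATION_ITERATIONS,
    seed: int = 0,
) -> CellTable:
    """Convenience chain: background-correct → dilate → per-cell means."""
    corrected = background_correct(stack)
    dilated = dilate_mask(mask, iterations=dilate_iterations, seed=seed)
    return mean_expression(corrected, dilated)
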