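"""Per-cell image patches for the morphology featurizer.

For each cell and each measured marker, three 224×224 channels:

1. *cell only* — the cell's masked pixels, bounding box rescaled 3×
   (bilinear), centered on a zero canvas (center-cropped if the rescaled
   box exceeds 224);
2. *context 1×* — a 224 px crop centered on the cell centroid at native
   scale (≈84.6 µm at 0.3775 µm/px);
3. *context 0.5×* — a 448 px centered crop downsampled to 224
   (≈169 µm field).

Out-of-bounds regions are zero-padded.  Channels are stacked marker-major:
for P measured markers the tensor is 224×224×3P (21 deep for a 7-plex).
All channels are contrast-normalized to [0, 1] beforehand with a two-tail
percentile stretch (``autoadjust``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize

from sevenup.exceptions import DimensionMismatchError, SevenUpError
from sevenup.io_formats import MarkerImageStack, SegmentationMask

logger = logging.getLogger(__name__)

PATCH_SIZE = 224
CELL_SCALE = 3.0
CONTEXT_HALF_SCALE_FIELD = 2 * PATCH_SIZE  # 448 px field → ×0.5 → 224
AUTOADJUST_SATURATION = 0.0035  # fraction saturated at each tail


def autoadjust(channel: np.ndarray, saturation: float = AUTOADJUST_SATURATION) -> np.ndarray:
    """Two-tail percentile contrast stretch onto [0, 1].

    The lowest and highest ``saturation`` fraction of pixels are clipped;
    the remaining range maps linearly to [0, 1].  A constant image maps to
    all zeros with a logged notice.
    """
    channel = np.asarray(channel, dtype=np.float64)
    lo = np.percentile(channel, 100.0 * saturation)
    hi = np.percentile(channel, 100.0 * (1.0 - saturation))
    if hi <= lo:
        logger.info("autoadjust: constant channel; mapping to zeros")
        return np.zeros_like(channel)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def _centered_crop(img: np.ndarray, cy: float, cx: float, size: int) -> np.ndarray:
    """size×size crop centered at (cy, cx), zero-padded beyond the borders."""
    out = np.zeros((size, size), dtype=img.dtype)
    half = size // 2
    y0 = int(round(cy)) - half
    x0 = int(round(cx)) - half
    ys0, ys1 = max(0, y0), min(img.shape[0], y0 + size)
    xs0, xs1 = max(0, x0), min(img.shape[1], x0 + size)
    if ys1 > ys0 and xs1 > xs0:
        out[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = img[ys0:ys1, xs0:xs1]
    return out


def _center_on_canvas(img: np.ndarray, size: int) -> np.ndarray:
    """Place (or center-crop) an image onto a size×size zero canvas."""
    h, w = img.shape
    if h > size:
        top = (h - size) // 2
        img = img[top : top + size]
        h = size
    if w > size:
        left = (w - size) // 2
        img = img[:, left : left + size]
        w = size
    out = np.zeros((size, size), dtype=img.dtype)
    y0 = (size - h) // 2
    x0 = (size - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = img
    return out


@dataclass
class PatchConfig:
    patch_size: int = PATCH_SIZE
    cell_scale: float = CELL_SCALE
    saturation: float = AUTOADJUST_SATURATION
    use_context: bool = True  # False → context channels zeroed (ablation input)


def extract_cell_patch(
    channel: np.ndarray,
    mask_pixels: tuple[np.ndarray, np.ndarray],
    centroid: tuple[float, float],
    config: PatchConfig,
) -> np.ndarray:
    """The three channels for one (cell, marker) pair; shape (3, S, S)."""
    size = config.patch_size
    ys, xs = mask_pixels
    # channel 1: masked cell, bbox rescaled cell_scale×, centered
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    box = np.zeros((y1 - y0, x1 - x0), dtype=np.float64)
    box[ys - y0, xs - x0] = channel[ys, xs]
    scaled_shape = (
        max(1, int(round(box.shape[0] * config.cell_scale))),
        max(1, int(round(box.shape[1] * config.cell_scale))),
    )
    scaled = resize(box, scaled_shape, order=1, anti_aliasing=False, preserve_range=True)
    cell_only = _center_on_canvas(scaled, size)
    if not config.use_context:
        zeros = np.zeros((size, size))
        return np.stack([cell_only, zeros, zeros])
    # channel 2: native-scale centered crop
    cy, cx = centroid
    ctx1 = _centered_crop(channel, cy, cx, size)
    # channel 3: double-field crop downsampled ×0.5 (exact 2×2 block average)
    ctx_half = _centered_crop(channel, cy, cx, 2 * size)
    ctx05 = ctx_half.reshape(size, 2, size, 2).mean(axis=(1, 3))
    return np.stack([cell_only, ctx1, ctx05])


def extract_patches(
    stack: MarkerImageStack,
    mask: SegmentationMask,
    cell_labels: Sequence[int],
    measured_markers: Sequence[str],
    config: PatchConfig | None = None,
) -> np.ndarray:
    """Patch tensors for the given cells: shape (n_cells, 3·P, S, S) in [0, 1].

    Channels are marker-major: for each measured marker in order,
    [cell-only, context 1×, context 0.5×].  Marker channels are autoadjusted
    over the whole sample before cropping.
    """
    config = config or PatchConfig()
    if mask.labels.shape != stack.shape:
        raise DimensionMismatchError(
            f"mask shape {mask.labels.shape} != image shape {stack.shape}"
        )
    adjusted = {
        m: autoadjust(stack.channels[m], config.saturation) for m in measured_markers
    }
    pixel_index = _label_pixel_index(mask, cell_labels)
    n = len(cell_labels)
    depth = 3 * len(measured_markers)
    out = np.zeros((n, depth, config.patch_size, config.patch_size), dtype=np.float32)
    for i, lab in enumerate(cell_labels):
        ys, xs = pixel_index[int(lab)]
        centroid = (float(ys.mean()), float(xs.mean()))
        for j, m in enumerate(measured_markers):
            out[i, 3 * j : 3 * j + 3] = extract_cell_patch(
                adjusted[m], (ys, xs), centroid, config
            )
    return out


def _label_pixel_index(
    mask: SegmentationMask, cell_labels: Iterable[int]
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    wanted = set(int(x) for x in cell_labels)
    ys, xs = np.nonzero(mask.labels)
    labs = mask.labels[ys, xs]
    order = np.argsort(labs, kind="stable")
    ys, xs, labs = ys[order], xs[order], labs[order]
    uniq, starts = np.unique(labs, return_index=True)
    ends = np.r_[starts[1:], labs.size]
    spans = {int(u): (int(s), int(e)) for u, s, e in zip(uniq, starts, ends)}
    index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for lab in wanted:
        if lab not in spans:
            raise SevenUpError(f"cell label {lab} not present in mask")
        s, e = spans[lab]
        index[lab] = (ys[s:e], xs[s:e])
    return index


def pool_patches(patches: np.ndarray, out_size: int) -> np.ndarray:
    """Downsample patch tensors (n, C, S, S) → (n, C, out, out) by area averaging.

    The featurizer's small backbone trains on pooled inputs; pooling is a
    front-end of the network, not a change to the stored patch geometry.
    """
    n, c, s, _ = patches.shape
    if s % out_size == 0:
        f = s // out_size
        return patches.reshape(n, c, out_size, f, out_size, f).mean(axis=(3, 5))
    out = np.empty((n, c, out_size, out_size), dtype=patches.dtype)
    for i in range(n):
        for j in range(c):
            out[i, j] = resize(
                patches[i, j], (out_size, out_size), order=1,
                anti_aliasing=True, preserve_range=True,
            )
    return out
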