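"""Readers and writers for every external artifact.

Images and masks travel as TIFF (single multi-page file with a channel-name
sidecar, or a directory of per-marker files); cell tables as CSV; panel
manifests and configs as YAML; fitted model bundles as zip archives with a
format-version field.  Channel identity is always resolved by marker *name*,
never by storage index, so permuting file order cannot change results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from sevenup.exceptions import (
    DimensionMismatchError,
    DuplicateKeyError,
    MissingMarkerError,
    NoCellsError,
    SevenUpError,
)

logger = logging.getLogger(__name__)

#: native acquisition resolution, microns per pixel
DEFAULT_MICRONS_PER_PIXEL = 0.3775

KEY_COLUMNS = ["sample_id", "cell_label"]
META_COLUMNS = ["sample_id", "cell_label", "coverslip_id", "centroid_x", "centroid_y"]
RAW_PREFIX = "raw_"
NORM_PREFIX = "norm_"


# ---------------------------------------------------------------------------
# Panel manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelManifest:
    """Ordered full marker panel split into measured and imputed subsets.

    ``measured_markers`` is the small experimentally imaged panel (size P,
    canonically 7); ``imputed_markers`` is the complement, in ``all_markers``
    order.
    """

    all_markers: tuple[str, ...]
    measured_markers: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "all_markers", tuple(self.all_markers))
        object.__setattr__(self, "measured_markers", tuple(self.measured_markers))
        if len(set(self.all_markers)) != len(self.all_markers):
            raise SevenUpError("marker names must be unique")
        unknown = set(self.measured_markers) - set(self.all_markers)
        if unknown:
            raise MissingMarkerError(
                f"measured markers not in panel: {sorted(unknown)}"
            )
        if len(set(self.measured_markers)) != len(self.measured_markers):
            raise SevenUpError("measured markers must be distinct")
        p = len(self.measured_markers)
        if not (1 <= p < len(self.all_markers)):
            raise SevenUpError(
                f"need 1 <= P < n_markers, got P={p}, n={len(self.all_markers)}"
            )

    @property
    def imputed_markers(self) -> tuple[str, ...]:
        measured = set(self.measured_markers)
        return tuple(m for m in self.all_markers if m not in measured)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "all_markers": list(self.all_markers),
            "measured_markers": list(self.measured_markers),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelManifest":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            all_markers=tuple(payload["all_markers"]),
            measured_markers=tuple(payload["measured_markers"]),
        )


# ---------------------------------------------------------------------------
# Image stack and segmentation mask
# ---------------------------------------------------------------------------


@dataclass
class MarkerImageStack:
    """Aligned per-marker intensity images for one sample.

    ``blank_first`` / ``blank_last`` are fluorophore-free autofluorescence
    images acquired in the first and last cycle; together with
    ``cycle_index`` (marker → acquisition cycle, 0-based) and ``n_cycles``
    they drive background correction.
    """

    channels: dict[str, np.ndarray]
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    sample_id: str = "sample"
    coverslip_id: str = "coverslip"
    cycle_index: dict[str, int] = field(default_factory=dict)
    n_cycles: int | None = None
    blank_first: np.ndarray | None = None
    blank_last: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise SevenUpError("microns_per_pixel must be positive")
        shapes = {m: img.shape for m, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise DimensionMismatchError(f"channel shapes differ: {shapes}")
        for blank, name in ((self.blank_first, "blank_first"), (self.blank_last, "blank_last")):
            if blank is not None and blank.shape != self.shape:
                raise DimensionMismatchError(
                    f"{name} shape {blank.shape} != channel shape {self.shape}"
                )

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def asarray(self, markers: Iterable[str] | None = None) -> np.ndarray:
        """Stack channels into (C, H, W) in the given (or stored) order."""
        names = tuple(markers) if markers is not None else self.markers
        missing = [m for m in names if m not in self.channels]
        if missing:
            raise MissingMarkerError(f"markers not in stack: {missing}")
        return np.stack([self.channels[m] for m in names])


@dataclass
class SegmentationMask:
    """Integer-labeled cell mask: 0 = background, k > 0 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SevenUpError("mask must be 2-D")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise SevenUpError("mask must be integer-typed")
        if (self.labels < 0).any():
            raise SevenUpError("mask labels must be nonnegative")

    @property
    def cell_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.size)

    def require_cells(self) -> None:
        if self.n_cells == 0:
            raise NoCellsError("segmentation mask contains no labeled cells")


def read_stack(path: str | Path, manifest: PanelManifest) -> MarkerImageStack:
    """Read a marker image stack, channels ordered per the manifest.

    ``path`` may be a directory of per-marker TIFFs (``<marker>.tif``) or a
    single multi-page TIFF accompanied by a ``<name>.channels.yaml`` sidecar
    listing page names.  Channel-name metadata conventions vary, so the
    sidecar is authoritative for multi-page files.
    """
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    if path.is_dir():
        for marker in manifest.all_markers:
            candidates = [path / f"{marker}.tif", path / f"{marker}.tiff"]
            found = next((c for c in candidates if c.exists()), None)
            if found is None:
                raise MissingMarkerError(f"no image for marker {marker!r} in {path}")
            channels[marker] = tifffile.imread(found)
    else:
        sidecar = path.with_suffix(path.suffix + ".channels.yaml")
        if not sidecar.exists():
            raise SevenUpError(
                f"multi-page stack {path} needs a channel-name sidecar {sidecar.name}"
            )
        names = list(yaml.safe_load(sidecar.read_text()))
        data = tifffile.imread(path)
        data = np.atleast_3d(data)
        if data.shape[0] != len(names):
            raise DimensionMismatchError(
                f"{path}: {data.shape[0]} pages but {len(names)} channel names"
            )
        by_name = {n: data[i] for i, n in enumerate(names)}
        for marker in manifest.all_markers:
            if marker not in by_name:
                raise MissingMarkerError(f"marker {marker!r} missing from {path}")
            channels[marker] = by_name[marker]
    return MarkerImageStack(channels=channels)


def write_stack(stack: MarkerImageStack, path: str | Path, multi_page: bool = False) -> None:
    """Write a stack as per-marker TIFFs in a directory, or one multi-page TIFF."""
    path = Path(path)
    if multi_page:
        names = list(stack.markers)
        tifffile.imwrite(
            path,
            np.stack([stack.channels[m] for m in names]),
            photometric="minisblack",  # channels are marker planes, not RGB
        )
        sidecar = path.with_suffix(path.suffix + ".channels.yaml")
        sidecar.write_text(yaml.safe_dump(names))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for marker, img in stack.channels.items():
            tifffile.imwrite(path / f"{marker}.tif", img)


def read_mask(path: str | Path) -> SegmentationMask:
    return SegmentationMask(labels=tifffile.imread(path).astype(np.int32))


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------


@dataclass
class CellTable:
    """Per-cell records keyed by (sample_id, cell_label).

    Wraps a :class:`pandas.DataFrame` with columns ``sample_id``,
    ``cell_label``, ``coverslip_id``, ``centroid_x``, ``centroid_y``,
    per-marker ``raw_<marker>`` and (after normalization) ``norm_<marker>``
    expression, plus optional ``cell_type`` and ``cluster_id``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.df.columns]
        if missing:
            raise SevenUpError(f"cell table missing key columns: {missing}")
        if self.df.duplicated(KEY_COLUMNS).any():
            dupes = self.df.loc[self.df.duplicated(KEY_COLUMNS), KEY_COLUMNS]
            raise DuplicateKeyError(
                f"duplicate (sample_id, cell_label) keys: {dupes.values[:5].tolist()}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(
            c[len(RAW_PREFIX):] for c in self.df.columns if c.startswith(RAW_PREFIX)
        )

    @property
    def normalized_markers(self) -> tuple[str, ...]:
        return tuple(
            c[len(NORM_PREFIX):] for c in self.df.columns if c.startswith(NORM_PREFIX)
        )

    def raw_matrix(self, markers: Iterable[str]) -> np.ndarray:
        return self._matrix(RAW_PREFIX, markers)

    def norm_matrix(self, markers: Iterable[str]) -> np.ndarray:
        return self._matrix(NORM_PREFIX, markers)

    def _matrix(self, prefix: str, markers: Iterable[str]) -> np.ndarray:
        cols = [prefix + m for m in markers]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise MissingMarkerError(f"cell table missing columns: {missing}")
        return self.df[cols].to_numpy(dtype=np.float64)

    def subset(self, mask: np.ndarray | pd.Series) -> "CellTable":
        return CellTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    @staticmethod
    def concat(tables: Iterable["CellTable"]) -> "CellTable":
        return CellTable(pd.concat([t.df for t in tables], ignore_index=True))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """CSV is the canonical interchange format; ``.parquet`` paths use the
    columnar binary alternative."""
    path = Path(path)
    if path.suffix == ".parquet":
        table.df.to_parquet(path, index=False)
    else:
        table.df.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> CellTable:
    path = Path(path)
    if path.suffix == ".parquet":
        return CellTable(pd.read_parquet(path))
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "coverslip_id": str, "cell_type": str},
    )
    if "cell_label" in df.columns:
        df["cell_label"] = df["cell_label"].astype(np.int64)
    if "cluster_id" in df.columns:
        df["cluster_id"] = df["cluster_id"].astype(np.int64)
    return CellTable(df)


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_config(config: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# Model bundles (delegates to the owning classes; kept here so all artifact
# I/O has one home)
# ---------------------------------------------------------------------------


def save_bundle(bundle, path: str | Path) -> None:
    """Save a fitted :class:`sevenup.impute.ImputationBundle` archive."""
    bundle.save(path)


def load_bundle(path: str | Path):
    from sevenup.impute import ImputationBundle

    return ImputationBundle.load(path)
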