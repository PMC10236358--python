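import numpy as np
import pandas as pd
import pytest

from sevenup.io_formats import CellTable, PanelManifest
from sevenup.synthetic import CellTypeSpec, TissueRecipe


@pytest.fixture
def tiny_manifest() -> PanelManifest:
    return PanelManifest(
        all_markers=("A", "B", "C", "D"), measured_markers=("A", "B")
    )


@pytest.fixture
def two_type_recipe() -> TissueRecipe:
    """Two well-separated expression types, no noise sources beyond placement."""
    types = (
        CellTypeSpec(
            name="alpha", prevalence=0.5, radius=3.0,
            mean_expression={"A": 5.0, "B": 1.0, "C": 4.0, "D": 1.0},
        ),
        CellTypeSpec(
            name="beta", prevalence=0.5, radius=3.0,
            mean_expression={"A": 1.0, "B": 5.0, "C": 1.0, "D": 4.0},
        ),
    )
    return TissueRecipe(
        markers=("A", "B", "C", "D"),
        n_cells=60,
        image_size=(160, 160),
        cell_types=types,
        seed=11,
    )


def make_cell_table(n: int = 10, markers: tuple[str, ...] = ("A", "B"),
                    seed: int = 0, sample_id: str = "s0") -> CellTable:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_label": np.arange(1, n + 1, dtype=np.int64),
            "coverslip_id": "c0",
            "centroid_x": rng.uniform(0, 100, n),
            "centroid_y": rng.uniform(0, 100, n),
        }
    )
    for m in markers:
        df[f"raw_{m}"] = rng.gamma(2.0, 2.0, n)
    return CellTable(df)
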