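import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cytomc.core import CellTable, MarkerPanel


@pytest.fixture
def small_panel() -> MarkerPanel:
    """Six-marker panel: 4 clustering markers plus kappa/lambda."""
    names = ("M0", "M1", "M2", "M3", "Kappa", "Lambda")
    mask = (True, True, True, True, False, False)
    return MarkerPanel(names, kappa_index=4, lambda_index=5, clustering_mask=mask)


def make_cells(values, sample_id=None, batch_id=None, is_control=None,
               markers=None, scale="raw", truth=None) -> CellTable:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return CellTable(
        values=values,
        marker_names=tuple(markers) if markers else tuple(f"M{i}" for i in range(m)),
        sample_id=np.asarray(sample_id if sample_id is not None else ["s0"] * n),
        batch_id=np.asarray(batch_id if batch_id is not None else ["b0"] * n),
        is_control=np.asarray(is_control if is_control is not None else [False] * n),
        scale=scale,
        truth=None if truth is None else pd.DataFrame(truth),
    )


@pytest.fixture
def cells_factory():
    return make_cells
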