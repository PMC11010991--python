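import numpy as np
import pandas as pd
import pytest

from spatialcn import (
    CNConfig,
    SyntheticConfig,
    assign_cell_types,
    default_gating_scheme,
    fit_neighborhoods,
    generate_cohort,
)
from spatialcn.phenotyping import MARKERS
from spatialcn.synthetic_data import default_thresholds


def make_cells(xy, types, spot_id="S1", patient_id="P1", ids=None):
    """Hand-built single-spot cell table from coordinates and type labels."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    ids = ids if ids is not None else [f"c{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "cell_id": ids,
            "patient_id": patient_id,
            "spot_id": spot_id,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cell_type": list(types),
        }
    )
    return df


@pytest.fixture(scope="session")
def micro_cohort():
    """4-patient cohort, small spots; shared across read-only tests."""
    cfg = SyntheticConfig(n_patients=4, cells_per_spot=(400, 600), seed=7)
    cells, survival, gt = generate_cohort(cfg)
    return cfg, cells, survival, gt


@pytest.fixture(scope="session")
def labeled_micro_cohort(micro_cohort):
    cfg, cells, survival, gt = micro_cohort
    scheme = default_gating_scheme(default_thresholds())
    labeled_in = assign_cell_types(cells, scheme)
    labeled, model = fit_neighborhoods(labeled_in, CNConfig(clustering_seed=7))
    return labeled, model, survival, gt


@pytest.fixture()
def gating_scheme():
    return default_gating_scheme(default_thresholds())


def intensity_row(positive=(), base=5.0, hot=60.0):
    """One cell's intensity dict: `hot` for DAPI + the given markers."""
    row = {}
    for m in MARKERS:
        row[f"{m}_intensity"] = hot if (m == "DAPI" or m in positive) else base
    return row
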