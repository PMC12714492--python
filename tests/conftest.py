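import numpy as np
import pandas as pd
import pytest

from tigerocc.model import LatentState, ModelParameters
from tigerocc.survey_data import SurveyDataset


def make_dataset(grids_spec, subgrids_spec, standardized=True):
    """Build a SurveyDataset from terse specs.

    grids_spec: dict grid_id -> (prey_km, ndvi, hpd, elev) or shorter tuple
    (missing covariates default to 0).
    subgrids_spec: dict subgrid_id -> dict with grid_id, effort, tiger_det,
    prey_det and optional covariates.
    """
    grows = {}
    for gid, cov in grids_spec.items():
        cov = tuple(cov) + (0.0,) * (4 - len(cov))
        grows[gid] = {"prey_km": cov[0], "ndvi": cov[1], "hpd": cov[2],
                      "elev": cov[3], "surveyed": True}
    grids = pd.DataFrame.from_dict(grows, orient="index")
    grids.index.name = "grid_id"
    srows = {}
    for sid, spec in subgrids_spec.items():
        row = {"grid_id": spec["grid_id"], "effort": spec.get("effort", 0),
               "tiger_det": spec.get("tiger_det", 0),
               "prey_det": spec.get("prey_det", 0),
               "ndvi": spec.get("ndvi", 0.0), "hpd": spec.get("hpd", 0.0),
               "elev": spec.get("elev", 0.0),
               "in_buffer": spec.get("in_buffer", False)}
        srows[sid] = row
    subs = pd.DataFrame.from_dict(srows, orient="index")
    subs.index.name = "subgrid_id"
    scaling = None
    if standardized:
        scaling = {f"grid:{f}": (0.0, 1.0)
                   for f in ("prey_km", "ndvi", "hpd", "elev")}
        scaling.update({f"subgrid:{f}": (0.0, 1.0)
                        for f in ("ndvi", "hpd", "elev")})
    return SurveyDataset(grids, subs, scaling)


@pytest.fixture
def one_cell_dataset():
    """1 grid, 1 subgrid, 2 segments of effort, one tiger sign."""
    return make_dataset(
        {"g1": (0.0,)},
        {"s1": {"grid_id": "g1", "effort": 2, "tiger_det": 1, "prey_det": 0}},
    )


@pytest.fixture
def small_dataset():
    """2 grids x 2 subgrids with nonzero covariates and mixed detections
    (10 latent bits, enumerable)."""
    return make_dataset(
        {"g1": (0.5, 0.2, -0.3, 0.1), "g2": (-0.5, -0.2, 0.3, -0.1)},
        {
            "s1": {"grid_id": "g1", "effort": 4, "tiger_det": 1,
                   "prey_det": 2, "ndvi": 0.4, "hpd": -0.2, "elev": 0.3},
            "s2": {"grid_id": "g1", "effort": 3, "tiger_det": 0,
                   "prey_det": 0, "ndvi": -0.6, "hpd": 0.1, "elev": -0.5},
            "s3": {"grid_id": "g2", "effort": 5, "tiger_det": 0,
                   "prey_det": 3, "ndvi": 0.2, "hpd": 0.5, "elev": -0.2},
            "s4": {"grid_id": "g2", "effort": 0, "tiger_det": 0,
                   "prey_det": 0, "ndvi": -0.1, "hpd": -0.4, "elev": 0.6},
        },
    )


@pytest.fixture
def zero_params():
    return ModelParameters.zeros()


@pytest.fixture
def all_ones_latent():
    def _make(n_grids, n_subgrids):
        return LatentState(np.ones(n_grids, np.int8),
                           np.ones(n_subgrids, np.int8),
                           np.ones(n_subgrids, np.int8))
    return _make
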