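import warnings

import numpy as np
import pandas as pd
import pytest

from crabmap.core_io import CRS, Affine, GridRaster
from crabmap.sdm import BinaryRange
from crabmap.synthetic_landscape import SYNTH_CRS, LandscapeConfig, generate_landscape
from crabmap.pipeline import run_pipeline


def km_template(nrows: int, ncols: int, cell_km: float = 1.0) -> GridRaster:
    """Projected equal-area template with (0,0) at the southwest corner."""
    cell_m = cell_km * 1000.0
    return GridRaster(np.zeros((nrows, ncols)),
                      Affine.north_up(0.0, nrows * cell_m, cell_m, cell_m),
                      CRS("EPSG:6933"))


def binary_range(name: str, template: GridRaster, presence: np.ndarray) -> BinaryRange:
    return BinaryRange(name, template.like(np.asarray(presence, dtype=float)),
                       "modelled", n_records=1)


def occurrence_frame(species, xs, ys, vague=None, crs=SYNTH_CRS) -> pd.DataFrame:
    df = pd.DataFrame({
        "species": species, "lon": xs, "lat": ys,
        "vague": vague if vague is not None else False,
        "source": "test",
    })
    df.attrs["crs"] = crs
    return df


@pytest.fixture(scope="session")
def small_truth():
    cfg = LandscapeConfig(shape=(64, 64), n_species=10, n_basins_coarse=8,
                          n_basins_fine=24, seed=11)
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full chain at the default study scale (128x128, 20 species)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(LandscapeConfig(seed=1), replicates=3)
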