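"""Shared fixtures: tiny hand-built grids and one mid-sized synthetic landscape."""

import numpy as np
import pytest

from stoclcc.grids import (
    DEFORESTED,
    FOREST,
    NODATA,
    REGEN,
    FeatureLayers,
    LandCoverGrid,
    build_series,
)


def grid_from_codes(codes, year=2000, cell_size=30.0):
    return LandCoverGrid(year, np.asarray(codes, dtype=np.int8), cell_size)


@pytest.fixture
def tiny_features():
    """5x5 features: a road column, a river row, one settlement, a protected corner."""
    shape = (5, 5)
    roads = np.zeros(shape, dtype=bool)
    roads[:, 0] = True
    rivers = np.zeros(shape, dtype=bool)
    rivers[4, :] = True
    settlements = np.zeros(shape, dtype=bool)
    settlements[0, 4] = True
    protected = np.zeros(shape, dtype=bool)
    protected[:2, :2] = True
    return FeatureLayers(roads, rivers, settlements, protected)


@pytest.fixture(scope="session")
def recovery_scenario():
    """One 100x100 synthetic landscape with a single annual calibration interval."""
    from stoclcc.synth import SyntheticScenario, generate_truth_series

    scenario = SyntheticScenario(shape=(100, 100), seed=42, years=(1986, 2000, 2001))
    series = generate_truth_series(scenario)
    return scenario, series
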