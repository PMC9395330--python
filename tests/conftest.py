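import numpy as np
import pandas as pd
import pytest

import reeftrack as rt


@pytest.fixture
def toy_track() -> pd.DataFrame:
    """Four fixes / three movement steps with depth, minutes apart."""
    return pd.DataFrame(
        {
            "fish_id": "f1",
            "t": pd.to_datetime(
                [
                    "2016-05-01 00:00:00",
                    "2016-05-01 00:05:00",
                    "2016-05-01 00:12:00",
                    "2016-05-01 00:20:00",
                ],
                utc=True,
            ),
            "x": [0.0, 8.0, 3.0, -4.0],
            "y": [0.0, 5.0, 12.0, 6.0],
            "depth": [20.0, 22.0, 25.0, 21.0],
        }
    )


@pytest.fixture
def stationary_step() -> pd.DataFrame:
    """One zero-displacement step: the analytic-moment reference case."""
    return pd.DataFrame(
        {
            "fish_id": ["f1"],
            "t_start": [pd.Timestamp("2016-05-01", tz="UTC")],
            "dt": [1000.0],
            "x0": [50.0], "y0": [50.0], "z0": [np.nan],
            "x1": [50.0], "y1": [50.0], "z1": [np.nan],
            "s0": [0.0], "s1": [0.0],
        }
    )


@pytest.fixture
def flat_bathy() -> rt.BathymetryGrid:
    """100 x 100 m grid of uniform 30-m seabed, 10-m cells."""
    return rt.BathymetryGrid(x0=0.0, y0=0.0, cell=10.0, depth=np.full((10, 10), 30.0))


@pytest.fixture
def three_reefs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station_id": ["A", "B", "Q"],
            "kind": "reef",
            "x": [0.0, 100.0, 500.0],
            "y": [0.0, 0.0, 0.0],
            "surveyed": False,
        }
    )
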