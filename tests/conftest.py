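import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from flockdecide.movement_extraction import (STREAM_COLUMNS, MovementEvent,
                                             OccupancyVector)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_event(nc_dep, nh_dep, from_feeder, to_feeder, nc_arr=None, nh_arr=None,
               t_depart=100.0, t_arrive=115.0, species="great_tit", tag="focal"):
    """Build a movement event directly from occupancy counts (focal already
    excluded), bypassing stream extraction."""
    nc_dep = np.asarray(nc_dep, float)
    nh_dep = np.asarray(nh_dep, float)
    nc_arr = nc_dep if nc_arr is None else np.asarray(nc_arr, float)
    nh_arr = nh_dep if nh_arr is None else np.asarray(nh_arr, float)
    dep = OccupancyVector(nc_dep, nh_dep, window=(t_depart - 30, t_depart), focal_tag=tag)
    arr = OccupancyVector(nc_arr, nh_arr, window=(t_arrive - 30, t_arrive), focal_tag=tag)
    return MovementEvent(focal_tag=tag, focal_species=species,
                         from_feeder=from_feeder, to_feeder=to_feeder,
                         t_depart=t_depart, t_arrive=t_arrive,
                         occupancy_at_departure=dep, occupancy_at_arrival=arr)


@pytest.fixture
def toy_stream():
    """Worked toy patch: focal bird feeds at F1 for two intervals while one
    other bird sits at F2 and three at F3, then the focal turns up at F3.
    Expected: one F1->F3 movement with rho_leave = 0 and rho_arrive = 0.75
    (focal removed from its own occupancy context)."""
    rows = [("P1", t, 1, "focal", "great_tit") for t in (15, 30)]
    rows += [("P1", 60, 3, "focal", "great_tit")]
    for t in (15, 30, 45):
        rows.append(("P1", t, 2, "b1", "blue_tit"))
        for b in ("b2", "b3", "b4"):
            rows.append(("P1", t, 3, b, "blue_tit"))
    df = pd.DataFrame(rows, columns=STREAM_COLUMNS)
    return df.sort_values(["timestamp_s", "feeder_id", "tag_id"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_synthetic_stream():
    """A short generated session shared across extraction/pipeline tests."""
    from flockdecide.synthetic_data import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(seed=5, session_length=1800.0, n_individuals=300,
                          flock_arrival_rate=12.0)
    return cfg, generate_dataset(cfg)
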