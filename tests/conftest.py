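from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from icefox.simulate import ScenarioParams, default_scenario

T0 = datetime(2010, 11, 1, 10, 0, tzinfo=timezone.utc)


def make_traj(points, animal_id="A01", lc="3", error_radius=250.0):
    """Location table from (minutes, x, y) triples."""
    rows = [
        {
            "animal_id": animal_id,
            "timestamp": T0 + timedelta(minutes=float(m)),
            "x": float(x),
            "y": float(y),
            "lc": lc,
            "error_radius": error_radius,
        }
        for m, x, y in points
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20101025)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced synthetic study for fast end-to-end tests: fewer foxes, a
    shorter winter and fewer carcass sites than the full default scenario."""
    params = ScenarioParams(
        n_foxes=8,
        coast_km=24.0,
        start=date(2010, 11, 15),
        end=date(2011, 2, 15),
        n_planted=2,
        n_distractor=1,
        carcass_earliest=date(2010, 12, 1),
        carcass_latest_start=date(2011, 1, 10),
        planted_members=(3, 6),
    )
    locations, mask, truth = default_scenario(7, params)
    return params, locations, mask, truth
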