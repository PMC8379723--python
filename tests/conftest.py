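import numpy as np
import pandas as pd
import pytest

from pairforage import ColonyGeometry, SimConfig, simulate_pair


COLONY = ColonyGeometry(51.45, 3.7, 500.0)


def make_fixes(times_min, inside_flags, individual_id="b1", pair_id="p1",
               sex="male", colony=COLONY, step_km=5.0):
    """Fix table with given in/out-of-colony membership pattern.

    Out-of-colony fixes are placed ``step_km`` east of the colony centre,
    in-colony fixes at the centre.
    """
    t0 = pd.Timestamp("2016-06-01T00:00:00Z")
    rows = []
    deg_per_km = 1.0 / (111.19492664455873 * np.cos(np.radians(colony.centre_lat)))
    for m, inside in zip(times_min, inside_flags):
        rows.append(dict(
            individual_id=individual_id, pair_id=pair_id, sex=sex, colony_id="COL",
            timestamp=t0 + pd.Timedelta(minutes=float(m)),
            lat=colony.centre_lat,
            lon=colony.centre_lon + (0.0 if inside else step_km * deg_per_km),
        ))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def colony():
    return COLONY


@pytest.fixture(scope="session")
def small_sim_output():
    """One fully simulated pair over 3 days (movement + sensors)."""
    cfg = SimConfig(days=3.0, seed=12345)
    return simulate_pair(cfg, "P001")
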