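import hypothesis
import numpy as np
import pandas as pd
import pytest

from sympatry.synthetic import SimConfig, simulate_forager
from sympatry.trajectory import Trajectory

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None)
hypothesis.settings.load_profile("default")


def make_trajectory(xy, t_seconds, animal_id="t"):
    """Trajectory from planar coordinates and times (lon/lat left zeroed)."""
    xy = np.asarray(xy, dtype=float)
    t = pd.Timestamp("2019-03-15", tz="UTC") + pd.to_timedelta(
        np.asarray(t_seconds, dtype=float), unit="s")
    fixes = pd.DataFrame({"t": t, "lon": 0.0, "lat": 0.0,
                          "x": xy[:, 0], "y": xy[:, 1]})
    return Trajectory(animal_id, fixes)


@pytest.fixture
def traj_factory():
    return make_trajectory


@pytest.fixture(scope="session")
def resident_track():
    """One seeded range-resident simulated season, shared across tests."""
    return simulate_forager(SimConfig(seed=7))


@pytest.fixture(scope="session")
def short_track():
    """A 3-week resident track for geometry-heavy tests."""
    return simulate_forager(SimConfig(seed=11, n_days=21.0))
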