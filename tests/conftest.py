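import numpy as np
import pandas as pd
import pytest

from misi import SimConfig, SouthPolarLAEA, simulate_tracks
from misi.track import Behaviour, Dataset, Trip


@pytest.fixture(scope="session")
def proj():
    return SouthPolarLAEA()


def make_trip(xy, start="2001-02-01T00:00:00Z", interval_s=3600.0,
              trip_id="t1", individual_id="i1", lonlat=None):
    """Build a Trip directly from projected coordinates (lon/lat optional)."""
    xy = np.asarray(xy, dtype=float)
    t = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(xy)) * interval_s, unit="s")
    if lonlat is None:
        lon, lat = SouthPolarLAEA().inverse(xy[:, 0], xy[:, 1])
    else:
        lon, lat = lonlat
    df = pd.DataFrame(
        {
            "individual_id": individual_id,
            "trip_id": trip_id,
            "t": t,
            "lon": lon,
            "lat": lat,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "behaviour": Behaviour.UNCLASSIFIED,
        }
    )
    return Trip(trip_id, individual_id, df)


@pytest.fixture(scope="session")
def specialist_dataset():
    """Small fully-specialist synthetic population (shared across tests)."""
    cfg = SimConfig(n_individuals=4, trips_per_individual=4, dwell_fixes=12,
                    specialism=1.0, rng_seed=11)
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def generalist_dataset():
    cfg = SimConfig(n_individuals=4, trips_per_individual=4, dwell_fixes=12,
                    specialism=0.0, rng_seed=12)
    return simulate_tracks(cfg)


def tracks_csv(tmp_path, rows, name="tracks.csv", header="individual_id,trip_id,timestamp,lon,lat"):
    p = tmp_path / name
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p
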