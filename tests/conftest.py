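import numpy as np
import pandas as pd
import pytest

from pelagos.tracks import Colony

BIRD = Colony("BirdIsland", -54.000, -38.050)
PRION = Colony("PrionIsland", -54.0333, -37.4167)


@pytest.fixture(scope="session")
def colonies():
    return BIRD, PRION


def make_fixes(bird_id, start, hours, lats, lons, colony="BirdIsland"):
    """Hand-built fix table: positions at the given hour offsets."""
    t0 = pd.Timestamp(start, tz="UTC")
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "colony": colony,
            "timestamp": [t0 + pd.Timedelta(hours=float(h)) for h in hours],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def compact_trackset():
    """One seeded compact two-colony simulation shared across tests."""
    from pelagos import synthetic

    cfg = synthetic.compact_config(separation_deg=180.0, trips_per_colony=20)
    return cfg, synthetic.simulate_tracks(cfg, seed=7)
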