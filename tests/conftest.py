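"""Shared fixtures: small synthetic tracks and one larger simulated campaign."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from radarwatch.geotrack import DEVICE_XGPS, RADAR_NEGATIVE, RADAR_NOSCAN, RADAR_POSITIVE, Colony, Track

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

MALGAS = Colony(lat=-33.05, lon=17.93, radius_km=2.0)


def make_track(
    times_s,
    lats,
    lons,
    bird_id: str = "b1",
    device: str = DEVICE_XGPS,
    radar=None,
    t0: str = "2017-10-25T08:00:00Z",
) -> Track:
    """Build a Track from relative seconds and coordinate lists."""
    t0 = pd.Timestamp(t0)
    df = pd.DataFrame(
        {
            "time": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
            "radar": radar if radar is not None else RADAR_NOSCAN,
        }
    )
    return Track(bird_id, device, df)


def scan_track(pos_minutes, total_minutes: int | None = None, **kw) -> Track:
    """Stationary 1-min XGPS track with positive scans at the given minutes."""
    pos = set(int(m) for m in pos_minutes)
    n = (total_minutes if total_minutes is not None else (max(pos) if pos else 10) + 5) + 1
    radar = [RADAR_POSITIVE if m in pos else RADAR_NEGATIVE for m in range(n)]
    return make_track(
        [60 * m for m in range(n)], [-33.5] * n, [17.5] * n, radar=radar, **kw
    )


@pytest.fixture(scope="session")
def malgas() -> Colony:
    return MALGAS


@pytest.fixture(scope="session")
def sim_campaign(tmp_path_factory):
    """30 simulated XGPS trips with ground truth (defaults, fixed seed)."""
    from radarwatch.synthetic_data import SimConfig, generate_dataset

    cfg = SimConfig(seed=7, n_birds=30, xgps_fraction=1.0)
    out = tmp_path_factory.mktemp("sim30")
    paths = generate_dataset(cfg, out)
    return cfg, paths


@pytest.fixture(scope="session")
def null_campaign(tmp_path_factory):
    """Same campaign with attendance disabled (vessel avoidance only)."""
    from radarwatch.synthetic_data import SimConfig, generate_dataset

    cfg = SimConfig(seed=7, n_birds=30, xgps_fraction=1.0, p_attend_given_proximity=0.0)
    out = tmp_path_factory.mktemp("sim30null")
    paths = generate_dataset(cfg, out)
    return cfg, paths
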