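import logging

import numpy as np
import pandas as pd
import pytest

from socbackcast import rothc, scenario, spinup, world

logging.getLogger("socbackcast").setLevel(logging.ERROR)


@pytest.fixture
def arable_soil():
    return rothc.SoilParams(clay=8.0, land_use=rothc.LandUse.ARABLE)


@pytest.fixture
def temperate_cycle(arable_soil):
    """A periodic 12-month temperate forcing cycle (wet, mild seasonality)."""
    m = np.arange(12)
    season = -np.cos(2 * np.pi * (m + 0.5) / 12)
    temp = 9.0 + 7.0 * season
    precip = np.full(12, 70.0)
    pet = np.maximum(0.0, 20.0 + 40.0 * season)
    covered = np.ones(12, dtype=bool)
    return spinup.steady_cycle(temp, precip, pet, covered, arable_soil)


def make_site(row):
    return scenario.SiteRecord(
        site_id=str(row["site_id"]), lon=float(row["lon"]), lat=float(row["lat"]),
        soc_2018=float(row["soc_2018"]), clay=float(row["clay"]),
        land_use=rothc.LandUse(row["land_use"]), koppen_zone=str(row["koppen_zone"]),
    )


def cover_arrays(cover_row):
    w = cover_row[[f"w{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float)
    c = cover_row[[f"c{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float) > 0.5
    return w, c


@pytest.fixture(scope="session")
def small_world():
    """A 30-site default-condition synthetic world (sites, climate, cover)."""
    cfg = world.WorldConfig(n_sites=30, seed=42)
    return world.generate_world(cfg)


@pytest.fixture(scope="session")
def small_world_results(small_world):
    sites, climate, cover = small_world
    return scenario.backcast_sites(sites, climate, cover)


@pytest.fixture(scope="session")
def trendless_world():
    cfg = world.WorldConfig(
        n_sites=8, seed=7, warming_per_century=0.0, warming_sd_per_century=0.0,
        precip_trend_pct_per_century=0.0, precip_trend_sd_pct=0.0,
        temp_noise_sd=0.0, precip_noise_cv=0.0,
    )
    return world.generate_world(cfg)
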