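"""Synthetic input-bundle generator.

Emulates the statistical structure of the real driving data — spatially
varying topsoil SOC stocks and clay, monthly climate with seasonality, a
secular warming trend of order 1 °C per century, interannual noise, and
growing-season-weighted vegetation cover — so every pipeline stage can be
exercised without any download.  Sites are placed on a regular grid with
zone-dependent climate and SOC distributions; no spatial correlation or
realistic geography is attempted.

The defaults define the study conditions: 500 sites over ten Köppen zones,
a mean warming trend of 1.03 °C per century with site-to-site spread, no
mean precipitation trend, and potential evapotranspiration from a
Thornthwaite-style temperature formula so PET co-trends with warming.  The
wettest zones are configured with high enough rainfall that annual NPP is
temperature-limited there, while arid and continental zones are
water-limited, so both NPP branches are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenario import END_YEAR, N_YEARS, START_YEAR

__all__ = ["ZoneProfile", "ZONE_PROFILES", "WorldConfig", "generate_sites",
           "generate_climate", "generate_cover", "generate_world", "write_world"]


@dataclass(frozen=True)
class ZoneProfile:
    """Climatological template for one Köppen zone."""

    mat: float  # mean annual temperature, °C
    amplitude: float  # seasonal half-range of monthly temperature, °C
    map: float  # annual precipitation, mm
    soc_mean: float  # Mg C ha⁻¹
    lat: float  # representative latitude, degrees N
    winter_precip_share: float = 0.5  # 0 = all summer rain, 1 = all winter rain


# Zone templates: colder zones carry higher SOC (the familiar latitudinal
# pattern); the rainforest and hyperoceanic zones are wet enough to be
# temperature-limited for NPP.
ZONE_PROFILES: dict[str, ZoneProfile] = {
    "Af": ZoneProfile(mat=26.0, amplitude=1.5, map=5500.0, soc_mean=45.0, lat=4.0),
    "Aw": ZoneProfile(mat=25.0, amplitude=3.0, map=1200.0, soc_mean=35.0, lat=14.0, winter_precip_share=0.15),
    "BSh": ZoneProfile(mat=22.0, amplitude=8.0, map=400.0, soc_mean=20.0, lat=26.0, winter_precip_share=0.3),
    "BWk": ZoneProfile(mat=8.0, amplitude=14.0, map=200.0, soc_mean=15.0, lat=40.0),
    "Csa": ZoneProfile(mat=16.0, amplitude=9.0, map=600.0, soc_mean=30.0, lat=37.0, winter_precip_share=0.8),
    "Cfb": ZoneProfile(mat=9.5, amplitude=6.5, map=950.0, soc_mean=65.0, lat=50.0),
    "Cfc": ZoneProfile(mat=5.0, amplitude=5.0, map=4000.0, soc_mean=90.0, lat=56.0),
    "Dfb": ZoneProfile(mat=6.0, amplitude=14.0, map=700.0, soc_mean=70.0, lat=52.0),
    "Dfc": ZoneProfile(mat=0.5, amplitude=18.0, map=550.0, soc_mean=95.0, lat=61.0),
    "ET": ZoneProfile(mat=-3.0, amplitude=12.0, map=400.0, soc_mean=110.0, lat=68.0),
}


def _default_zone_mix() -> dict[str, float]:
    return {
        "Af": 0.08, "Aw": 0.12, "BSh": 0.10, "BWk": 0.06, "Csa": 0.10,
        "Cfb": 0.12, "Cfc": 0.08, "Dfb": 0.16, "Dfc": 0.12, "ET": 0.06,
    }


@dataclass
class WorldConfig:
    """Configuration of the synthetic world; the seed fixes all randomness."""

    n_sites: int = 500
    seed: int = 0
    zone_mix: dict[str, float] = field(default_factory=_default_zone_mix)
    soc_range: tuple[float, float] = (10.0, 150.0)
    clay_range: tuple[float, float] = (2.0, 60.0)
    soc_sd: float = 15.0  # site spread around the zone mean, Mg C ha⁻¹
    warming_per_century: float = 1.03  # mean secular temperature trend, °C
    warming_sd_per_century: float = 0.35  # site-to-site spread of the trend
    precip_trend_pct_per_century: float = 0.0  # mean precipitation trend, %
    precip_trend_sd_pct: float = 5.0  # site-to-site spread, % per century
    temp_noise_sd: float = 0.6  # interannual monthly temperature noise, °C
    precip_noise_cv: float = 0.25  # interannual monthly precipitation CV
    grassland_fraction: float = 0.3
    cover_threshold: float = 0.05  # monthly weight above which soil counts as covered

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be ≥ 1")
        if not self.zone_mix:
            raise ValueError("zone_mix must not be empty")
        total = sum(self.zone_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"zone_mix proportions must sum to 1, got {total}")
        unknown = set(self.zone_mix) - set(ZONE_PROFILES)
        if unknown:
            raise ValueError(f"no climate profile for zones {sorted(unknown)}")


def _rng(config: WorldConfig, stream: str, key: int = 0) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str.hash is salted per run)
    import zlib

    return np.random.default_rng([config.seed, zlib.crc32(stream.encode()), key])


def generate_sites(config: WorldConfig) -> pd.DataFrame:
    """Reproducible site table with zone-dependent SOC and clay."""
    rng = _rng(config, "sites")
    zones = list(config.zone_mix)
    counts = np.floor(np.array([config.zone_mix[z] for z in zones]) * config.n_sites).astype(int)
    # distribute the rounding remainder deterministically
    for i in range(config.n_sites - counts.sum()):
        counts[i % len(zones)] += 1
    rows = []
    side = int(np.ceil(np.sqrt(config.n_sites)))
    k = 0
    for zone, n in zip(zones, counts):
        prof = ZONE_PROFILES[zone]
        for _ in range(n):
            soc = float(np.clip(rng.normal(prof.soc_mean, config.soc_sd), *config.soc_range))
            clay = float(np.clip(rng.normal(22.0, 12.0), *config.clay_range))
            land_use = "grassland" if rng.random() < config.grassland_fraction else "arable"
            lon = -20.0 + 0.1 * (k % side)
            lat = prof.lat + 0.1 * (k // side)
            rows.append({
                "site_id": f"s{k:05d}", "lon": lon, "lat": lat,
                "soc_2018": round(soc, 3), "clay": round(clay, 2),
                "land_use": land_use, "koppen_zone": zone,
            })
            k += 1
    return pd.DataFrame(rows)


def thornthwaite_pet(temp_monthly: np.ndarray) -> np.ndarray:
    """Thornthwaite monthly PET (mm) from monthly temperature.

    The standard formulation: each year's heat index I = Σ(T/5)^1.514 over
    its months above freezing, exponent α(I), PET = 16·(10T/I)^α.  Because
    I is recomputed per year, PET co-trends with warming at a moderate
    sensitivity rather than exploding with T^α at fixed I.  Months at or
    below 0 °C evaporate nothing.  No day-length correction (12-hour days
    assumed), adequate for a synthetic world.
    """
    t = np.asarray(temp_monthly, dtype=float)
    if len(t) % 12:
        raise ValueError("temperature series must cover whole years")
    years = t.reshape(-1, 12)
    pos = np.maximum(years, 0.0)
    heat = np.sum((pos / 5.0) ** 1.514, axis=1)
    alpha = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * pos / heat[:, None]) ** alpha[:, None]
    pet[(years <= 0) | ~np.isfinite(pet)] = 0.0
    return pet.ravel()


def generate_climate(site: pd.Series, config: WorldConfig) -> pd.DataFrame:
    """Monthly climate 1919–2018 for one site.

    Sinusoidal seasonality around the zone mean, a linear secular trend
    (site-specific, drawn around the configured mean), Gaussian interannual
    noise, and Thornthwaite-style PET recomputed from each month's
    temperature.  Precipitation is truncated at zero.
    """
    prof = ZONE_PROFILES[site["koppen_zone"]]
    site_idx = int(str(site["site_id"]).lstrip("s"))
    rng = _rng(config, "climate", site_idx)
    warming = config.warming_per_century + config.warming_sd_per_century * rng.standard_normal()
    ptrend = (config.precip_trend_pct_per_century
              + config.precip_trend_sd_pct * rng.standard_normal()) / 100.0

    months = np.arange(12 * N_YEARS)
    frac_century = months / (12.0 * 100.0)
    season = -np.cos(2.0 * np.pi * (months % 12 + 0.5) / 12.0)  # peak in July
    temp = (prof.mat + prof.amplitude * season
            + warming * frac_century
            + config.temp_noise_sd * rng.standard_normal(len(months)))

    w = prof.winter_precip_share
    monthly_share = (1.0 - w) * (1.0 + season) / 12.0 + w * (1.0 - season) / 12.0
    precip = prof.map * monthly_share
    precip = precip * (1.0 + ptrend * frac_century)
    precip = precip * (1.0 + config.precip_noise_cv * rng.standard_normal(len(months)))
    precip = np.maximum(precip, 0.0)

    pet = thornthwaite_pet(temp)
    return pd.DataFrame({
        "site_id": site["site_id"],
        "year": START_YEAR + months // 12,
        "month": months % 12 + 1,
        "temp": temp,
        "precip": precip,
        "pet": pet,
    })


def generate_cover(site: pd.Series, config: WorldConfig) -> pd.Series:
    """Growing-season monthly cover weights (sum 1) and covered flags.

    Higher-latitude sites concentrate growth into a shorter season: the
    Gaussian season width shrinks with |lat|, so the peak monthly weight
    grows with latitude.  Tropical sites are effectively uniform.
    """
    lat = float(site["lat"])
    width = max(1.2, 6.0 - 0.06 * abs(lat))  # months
    m = np.arange(12)
    centre = 6.0 if lat >= 0 else 0.0  # July (or January in the south)
    dist = np.minimum(np.abs(m - centre), 12 - np.abs(m - centre))
    weights = np.exp(-0.5 * (dist / width) ** 2)
    weights = weights / weights.sum()
    covered = weights > config.cover_threshold
    out = {"site_id": site["site_id"]}
    out.update({f"w{i + 1:02d}": weights[i] for i in range(12)})
    out.update({f"c{i + 1:02d}": int(covered[i]) for i in range(12)})
    return pd.Series(out)


def generate_world(config: WorldConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(sites, climate, cover) tables for the configured world."""
    sites = generate_sites(config)
    climate = pd.concat(
        [generate_climate(row, config) for _, row in sites.iterrows()],
        ignore_index=True,
    )
    cover = pd.DataFrame([generate_cover(row, config) for _, row in sites.iterrows()])
    return sites, climate, cover


def write_world(config: WorldConfig, outdir: str | Path) -> dict[str, Path]:
    """Write sites.csv, climate.csv, cover.csv and a manifest.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites, climate, cover = generate_world(config)
    paths = {
        "sites": outdir / "sites.csv",
        "climate": outdir / "climate.csv",
        "cover": outdir / "cover.csv",
        "manifest": outdir / "manifest.yaml",
    }
    sites.to_csv(paths["sites"], index=False)
    climate.to_csv(paths["climate"], index=False, float_format="%.6g")
    cover.to_csv(paths["cover"], index=False, float_format="%.10g")
    manifest = {
        "generator": "socbackcast.world",
        "seed": config.seed,
        "n_sites": config.n_sites,
        "period": [START_YEAR, END_YEAR],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return paths
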