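"""Köppen–Geiger climate-zone codes used for site labelling and aggregation."""

from __future__ import annotations

# 30-class Köppen–Geiger code set, in conventional table order.
KOPPEN_ZONES: dict[str, str] = {
    "Af": "Tropical, rainforest",
    "Am": "Tropical, monsoon",
    "Aw": "Tropical, savannah",
    "BWh": "Arid, desert, hot",
    "BWk": "Arid, desert, cold",
    "BSh": "Arid, steppe, hot",
    "BSk": "Arid, steppe, cold",
    "Csa": "Temperate, dry summer, hot summer",
    "Csb": "Temperate, dry summer, warm summer",
    "Csc": "Temperate, dry summer, cold summer",
    "Cwa": "Temperate, dry winter, hot summer",
    "Cwb": "Temperate, dry winter, warm summer",
    "Cwc": "Temperate, dry winter, cold summer",
    "Cfa": "Temperate, no dry season, hot summer",
    "Cfb": "Temperate, no dry season, warm summer",
    "Cfc": "Temperate, no dry season, cold summer",
    "Dsa": "Cold, dry summer, hot summer",
    "Dsb": "Cold, dry summer, warm summer",
    "Dsc": "Cold, dry summer, cold summer",
    "Dsd": "Cold, dry summer, very cold winter",
    "Dwa": "Cold, dry winter, hot summer",
    "Dwb": "Cold, dry winter, warm summer",
    "Dwc": "Cold, dry winter, cold summer",
    "Dwd": "Cold, dry winter, very cold winter",
    "Dfa": "Cold, no dry season, hot summer",
    "Dfb": "Cold, no dry season, warm summer",
    "Dfc": "Cold, no dry season, cold summer",
    "Dfd": "Cold, no dry season, very cold winter",
    "ET": "Polar, tundra",
    "EF": "Polar, frost",
}

ZONE_ORDER: list[str] = list(KOPPEN_ZONES)


def validate_zone(code: str) -> str:
    if code not in KOPPEN_ZONES:
        raise ValueError(f"unknown Köppen–Geiger code {code!r}")
    return code
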