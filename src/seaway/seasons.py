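"""Season calendar and seeded random-stream derivation shared by all stages."""

from __future__ import annotations

import zlib

import numpy as np

SEASONS = ("summer", "autumn", "winter", "spring")

#: calendar months belonging to each season
SEASON_MONTHS = {
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
}

_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}


class SeasonError(ValueError):
    pass


def check_season(season: str) -> str:
    if season not in SEASONS:
        raise SeasonError(f"unknown season {season!r}; valid labels are {', '.join(SEASONS)}")
    return season


def season_of_month(month: int) -> str:
    """Season label containing a calendar month (1-12)."""
    if month not in _MONTH_TO_SEASON:
        raise SeasonError(f"month must be 1..12, got {month}")
    return _MONTH_TO_SEASON[month]


def season_year(month: int, year: int) -> tuple[str, int]:
    """Season label and season-year for a calendar (month, year).

    Winter spans the year boundary and is labelled with the year of its
    December, so January and February belong to the previous season-year.
    """
    season = season_of_month(month)
    if season == "winter" and month in (1, 2):
        return season, year - 1
    return season, year


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Per-module random stream derived from one master seed.

    The stream for ``name`` is ``SeedSequence([seed, crc32(name)])`` so that
    every generator in the pipeline is a pure function of the master seed and
    its own label, and streams for different labels are independent.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
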