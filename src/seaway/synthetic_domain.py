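"""Seeded synthetic coastal domains, ocean fields, virtual species, telemetry.

Everything downstream of this module runs on its output, so every generator
here is a pure function of its configuration and an integer seed.  Random
streams are split per generator via :func:`seaway.seasons.rng_for`.

The domain is a shelf corridor along one grid edge: depth increases smoothly
offshore, the analysis mask covers 0 < depth <= 200 m plus a one-cell fringe
deeper than 200 m, and latitude is affine in row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import geo
from .raster import Raster
from .seasons import SEASONS, check_season, rng_for, season_of_month

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDomainConfig",
    "VirtualSpecies",
    "ConfigurationError",
    "make_domain",
    "make_seasonal_fields",
    "simulate_telemetry",
    "default_hydrophones",
    "write_detections_csv",
    "write_sites_csv",
    "sites_table",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticDomainConfig:
    """Geometry and placement parameters of a synthetic shelf domain."""

    extent: tuple[int, int] = (200, 60)
    coast_orientation: str = "east"  # which grid edge is land
    shelf_width_km: float = 30.0
    latitude_range: tuple[float, float] = (34.0, 56.0)  # (south, north) degN
    spawning_attractor: tuple[int, int] = (180, 50)
    overwintering_attractor: tuple[int, int] = (20, 50)
    cell_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latitude_range[0] >= self.latitude_range[1]:
            raise ConfigurationError("latitude_range must be (south, north) with south < north")
        if self.coast_orientation not in ("east", "west"):
            raise ConfigurationError("coast_orientation must be 'east' or 'west'")


@dataclass
class VirtualSpecies:
    """True species-environment relationship used to simulate telemetry.

    ``response_coefficients[name] = (a, b)`` contributes ``a*x + b*x**2`` to
    the suitability logit for covariate ``name``.  Attraction covariates
    (``spawn_attr``, ``winter_attr``) are additionally multiplied by the
    season weight, so the species can be drawn toward an attractor in some
    seasons only.  Suitability is the logistic transform of the logit, hence
    always in [0, 1].
    """

    response_coefficients: dict[str, tuple[float, float]]
    intercept: float = 0.0
    season_weights: dict[str, float] = field(default_factory=dict)
    detection_rate: float = 2.0  # expected detections per day at an occupied site
    seed: int = 0

    def logit(self, covariates: pd.DataFrame, season: str) -> np.ndarray:
        check_season(season)
        w = self.season_weights.get(season, 1.0)
        out = np.full(len(covariates), float(self.intercept))
        for name, (a, b) in self.response_coefficients.items():
            if name not in covariates.columns:
                continue
            x = covariates[name].to_numpy(dtype=float)
            term = a * x + b * x**2
            if name in ("spawn_attr", "winter_attr"):
                term = w * term
            out += term
        return out

    def suitability(self, covariates: pd.DataFrame, season: str) -> np.ndarray:
        """True probability-of-use in [0, 1] for each covariate row."""
        from scipy.special import expit

        return expit(self.logit(covariates, season))


# ---------------------------------------------------------------------------
# domain construction
# ---------------------------------------------------------------------------


def make_domain(config: SyntheticDomainConfig) -> tuple[Raster, Raster]:
    """Build the bathymetry and latitude rasters for a synthetic shelf.

    Returns positive-down depth in metres and a latitude raster linear in
    row index (top row = northern bound).  The valid mask covers the shelf
    (0 < depth <= 200 m) plus a one-cell offshore fringe deeper than 200 m,
    so that the highest-cost depth class is represented.
    """
    rows, cols = config.extent
    if rows < 50 or cols < 20:
        raise ConfigurationError(f"extent must be at least 50x20 cells, got {rows}x{cols}")
    rng = rng_for(config.seed, "domain")

    # per-row shelf width: mean width modulated by smooth alongshore noise
    noise = gaussian_filter(rng.standard_normal(rows), sigma=10.0, mode="nearest")
    noise /= max(np.std(noise), 1e-12)
    width_cells = config.shelf_width_km / config.cell_size * (1.0 + 0.15 * noise)
    width_cells = np.clip(width_cells, 3.0, cols - 2.0)

    # offshore distance of each cell centre from the coast edge, in cells
    j = np.arange(cols, dtype=float) + 0.5
    if config.coast_orientation == "east":
        offshore = j[::-1][np.newaxis, :]
    else:
        offshore = j[np.newaxis, :]
    rel = offshore / width_cells[:, np.newaxis]
    depth = 200.0 * rel**1.3

    shelf = depth <= 200.0
    # one-cell fringe just beyond the shelf edge, so depth > 200 m cells exist
    fringe = np.zeros_like(shelf)
    for r in range(rows):
        on_shelf = np.flatnonzero(shelf[r])
        if on_shelf.size == 0:
            continue
        if config.coast_orientation == "east":
            c = on_shelf.min() - 1
        else:
            c = on_shelf.max() + 1
        if 0 <= c < cols:
            fringe[r, c] = True
    valid = (shelf & (depth > 0)) | (fringe & (depth > 200.0))

    bathymetry = Raster(depth, config.cell_size, (0.0, rows * config.cell_size), valid)

    south, north = config.latitude_range
    lat_rows = north - (north - south) * np.arange(rows) / (rows - 1)
    latitude = bathymetry.like(np.repeat(lat_rows[:, np.newaxis], cols, axis=1))

    for name, (r, c) in (
        ("spawning", config.spawning_attractor),
        ("overwintering", config.overwintering_attractor),
    ):
        inside = 0 <= r < rows and 0 <= c < cols
        if not inside or not valid[r, c] or depth[r, c] > 200.0:
            raise ConfigurationError(
                f"{name} attractor at cell ({r}, {c}) is not on a valid <=200 m cell"
            )
    return bathymetry, latitude


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Unit-variance spatially correlated noise (Gaussian blur of white noise)."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=corr, mode="nearest")
    return raw / max(np.std(raw), 1e-12)


def make_seasonal_fields(
    bathymetry: Raster,
    latitude: Raster,
    season: str,
    seed: int,
    correlation_length: float = 10.0,
    cold_break_lat: float = 51.0,
    year: int | None = None,
    temp_noise_sd: float = 0.4,
) -> dict[str, Raster]:
    """Seasonal near-bottom ocean fields on the domain grid.

    Temperature decreases with latitude and, in winter and spring, drops
    sharply north of ``cold_break_lat``.  Oxygen saturation is high with a
    low-oxygen pocket at the southern extreme.  Currents are weak
    (|u|, |v| <= 0.2 m/s) with spatially correlated structure.
    """
    check_season(season)
    bathymetry.require_same_geometry(latitude)
    rng = rng_for(seed, f"fields:{season}:{year}")
    lat = latitude.values
    south, north = float(lat.min()), float(lat.max())
    rel = (lat - south) / max(north - south, 1e-12)
    shape = bathymetry.shape

    temp = 10.8 - 4.0 * rel - 0.004 * np.minimum(bathymetry.values, 250.0)
    if season in ("winter", "spring"):
        temp = temp - 4.0 / (1.0 + np.exp(-(lat - cold_break_lat) / 0.4))
    elif season == "summer":
        temp = temp + 1.0
    temp = temp + temp_noise_sd * _smooth_noise(rng, shape, correlation_length)

    oxygen = 96.0 + 3.0 * _smooth_noise(rng, shape, correlation_length)
    oxygen = oxygen - 55.0 * np.exp(-(((lat - south) / 1.5) ** 2))
    oxygen = np.clip(oxygen, 0.0, 120.0)

    poleward = 0.04 if season in ("autumn", "winter") else -0.04
    u = 0.05 * _smooth_noise(rng, shape, correlation_length)
    v = poleward + 0.05 * _smooth_noise(rng, shape, correlation_length)
    u = np.clip(u, -0.2, 0.2)
    v = np.clip(v, -0.2, 0.2)

    return {
        "temp": bathymetry.like(temp),
        "oxygen": bathymetry.like(oxygen),
        "u_east": bathymetry.like(u),
        "v_north": bathymetry.like(v),
    }


# ---------------------------------------------------------------------------
# telemetry simulation
# ---------------------------------------------------------------------------


def default_hydrophones(bathymetry: Raster, n: int = 40, seed: int = 0) -> list[tuple[int, int]]:
    """Evenly spaced alongshore hydrophone sites on valid shelf cells."""
    rng = rng_for(seed, "hydrophones")
    rows = np.linspace(0, bathymetry.n_rows - 1, n).round().astype(int)
    sites = []
    for r in rows:
        cols = np.flatnonzero(bathymetry.valid_mask[r] & (bathymetry.values[r] <= 200.0))
        if cols.size == 0:
            continue
        sites.append((int(r), int(rng.choice(cols))))
    return sites


def simulate_telemetry(
    truth: VirtualSpecies,
    stack,
    hydrophones: list[tuple[int, int]],
    period: list[tuple[int, int]],
    seed: int,
    n_tags: int = 148,
):
    """Simulate acoustic detections of tagged fish at fixed hydrophone sites.

    Each month, each tag independently occupies one hydrophone site with
    probability proportional to the true suitability there for that month's
    season; occupied site-months emit Poisson-distributed detection events at
    ``truth.detection_rate`` per day, uniformly timed within the month.

    Parameters
    ----------
    stack
        A :class:`~seaway.covariates.CovariateStack` supplying covariate
        values at the hydrophone cells.
    period
        List of ``(year, month)`` pairs to simulate.
    """
    from .covariates import cell_covariates
    from .occurrence import DetectionEvent

    if len(hydrophones) < 10:
        raise ConfigurationError(f"need at least 10 hydrophones, got {len(hydrophones)}")
    valid = stack.depth.valid_mask
    for r, c in hydrophones:
        if not valid[r, c]:
            raise ConfigurationError(f"hydrophone at cell ({r}, {c}) is off the valid mask")

    rng = rng_for(seed, "telemetry")
    events: list[DetectionEvent] = []
    suit_cache: dict[tuple[str, int | None], np.ndarray] = {}
    for year, month in period:
        season = season_of_month(month)
        key = (season, year if (season, year) in stack.seasonal else None)
        if key not in suit_cache:
            cov = cell_covariates(stack, season, hydrophones, year=key[1])
            suit_cache[key] = truth.suitability(cov, season)
        suit = suit_cache[key]
        total = suit.sum()
        if total <= 0:
            continue
        probs = suit / total
        month_start = pd.Timestamp(year=year, month=month, day=1, tz="UTC")
        month_days = (month_start + pd.offsets.MonthEnd(1)).day
        for tag in range(n_tags):
            site = int(rng.choice(len(hydrophones), p=probs))
            if probs[site] == 0:
                continue
            n_det = rng.poisson(truth.detection_rate * month_days)
            if n_det < 1:
                continue
            offsets = np.sort(rng.uniform(0, month_days * 86400.0, size=n_det))
            for off in offsets:
                events.append(
                    DetectionEvent(
                        tag_id=f"tag{tag:04d}",
                        hydrophone_id=f"H{site:03d}",
                        timestamp=month_start + pd.Timedelta(seconds=float(off)),
                    )
                )
    return events


def sample_presence_cells(
    truth: VirtualSpecies, stack, season: str, n: int, seed: int
) -> list[tuple[int, int]]:
    """Draw ``n`` valid cells with probability proportional to true suitability.

    Used for virtual-species recovery experiments where presences come from
    the whole domain rather than a hydrophone array.
    """
    from .covariates import cell_covariates

    check_season(season)
    rng = rng_for(seed, f"presences:{season}")
    rows, cols = np.nonzero(stack.depth.valid_mask)
    cells = list(zip(rows.tolist(), cols.tolist()))
    cov = cell_covariates(stack, season, cells, year=None)
    suit = truth.suitability(cov, season)
    if suit.sum() <= 0:
        raise ConfigurationError("true suitability is zero everywhere; cannot draw presences")
    pick = rng.choice(len(cells), size=n, replace=True, p=suit / suit.sum())
    return [cells[i] for i in pick]


def sites_table(hydrophones: list[tuple[int, int]], latitude: Raster) -> pd.DataFrame:
    """Hydrophone site table (hydrophone_id, row, col, lon, lat)."""
    recs = []
    for i, (r, c) in enumerate(hydrophones):
        lon, lat = geo.cell_to_lonlat(latitude, r, c)
        recs.append({"hydrophone_id": f"H{i:03d}", "row": r, "col": c, "lon": lon, "lat": lat})
    return pd.DataFrame(recs)


def write_sites_csv(hydrophones: list[tuple[int, int]], latitude: Raster, path: str | Path) -> None:
    sites_table(hydrophones, latitude).to_csv(path, index=False)


def write_detections_csv(events, path: str | Path) -> None:
    """Detection events as CSV with ISO 8601 timestamps."""
    df = pd.DataFrame(
        {
            "tag_id": [e.tag_id for e in events],
            "hydrophone_id": [e.hydrophone_id for e in events],
            "timestamp": [e.timestamp.isoformat() for e in events],
        }
    )
    df.to_csv(path, index=False)
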