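"""Distribution products: probability surfaces, thresholded presence maps,
and latitudinal profiles with local (loess-style) smoothing."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import maxent_engine
from .covariates import CovariateStack, cell_covariates
from .maxent_engine import MaxEntModel
from .raster import Raster
from .seasons import SEASONS, check_season

logger = logging.getLogger(__name__)

__all__ = ["LatitudinalProfile", "predict_surface", "seasonal_surface",
           "threshold_map", "latitudinal_profile"]


def predict_surface(model: MaxEntModel, stack: CovariateStack, season: str) -> Raster:
    """Logistic probability-of-presence surface over all valid cells."""
    check_season(season)
    rows, cols = np.nonzero(stack.depth.valid_mask)
    cells = list(zip(rows.tolist(), cols.tolist()))
    cov = cell_covariates(stack, season, cells, year=None)
    logistic = maxent_engine.predict(model, cov).logistic
    out = np.full(stack.depth.shape, np.nan)
    out[rows, cols] = logistic
    return stack.depth.like(out)


def seasonal_surface(
    models: dict[str, MaxEntModel], stacks: dict[str, CovariateStack] | CovariateStack
) -> tuple[dict[str, Raster], Raster]:
    """Per-season logistic surfaces and their unweighted cellwise mean.

    ``stacks`` may be a single shared stack or one per season; each season's
    prediction uses its own attraction layer via the season rule.
    """
    missing = set(SEASONS) - set(models)
    if missing:
        raise ValueError(f"need a model for every season; missing {sorted(missing)}")
    surfaces = {}
    for season in SEASONS:
        stack = stacks[season] if isinstance(stacks, dict) else stacks
        surfaces[season] = predict_surface(models[season], stack, season)
    first = surfaces[SEASONS[0]]
    for s in surfaces.values():
        first.require_same_geometry(s)
    mean = first.like(np.mean([surfaces[s].values for s in SEASONS], axis=0))
    return surfaces, mean


def threshold_map(surface: Raster, threshold: float) -> Raster:
    """Binary presence map: 1 where logistic >= threshold, 0 elsewhere.

    Invalid cells stay invalid (NaN values)."""
    if threshold <= 0.0 or threshold >= 1.0:
        logger.warning("threshold %g is at or beyond the logistic boundary", threshold)
    binary = np.where(surface.values >= threshold, 1.0, 0.0)
    binary = np.where(surface.valid_mask, binary, np.nan)
    return surface.like(binary)


@dataclass
class LatitudinalProfile:
    """Smoothed mean of a quantity by latitude (one season)."""

    latitude: np.ndarray
    value: np.ndarray
    span: float
    season: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"latitude": self.latitude, "season": self.season, "value": self.value}
        )


def latitudinal_profile(
    layer: Raster,
    latitude: Raster,
    span: float = 0.3,
    min_count: int = 10,
    season: str | None = None,
    n_bins: int | None = None,
) -> LatitudinalProfile:
    """Latitude profile of a raster layer over valid cells.

    Cell values are binned by latitude (default: one bin per grid row),
    bins with fewer than ``min_count`` cells are dropped (logged), and the
    bin means are smoothed with degree-1 tricube locally weighted regression
    (``span`` = fraction of points in each local window).
    """
    layer.require_same_geometry(latitude)
    mask = layer.valid_mask & np.isfinite(layer.values)
    lats = latitude.values[mask]
    vals = layer.values[mask]
    if n_bins is None:
        n_bins = layer.n_rows
    edges = np.linspace(lats.min(), lats.max() + 1e-9, n_bins + 1)
    which = np.digitize(lats, edges) - 1
    centers, means = [], []
    n_dropped = 0
    for b in range(n_bins):
        sel = which == b
        if sel.sum() < min_count:
            n_dropped += int(sel.sum() > 0)
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(vals[sel].mean())
    if n_dropped:
        logger.info("dropped %d latitude bins below the %d-cell minimum", n_dropped, min_count)
    centers = np.asarray(centers)
    means = np.asarray(means)
    smoothed = lowess(means, centers, frac=span, it=0, return_sorted=False)
    return LatitudinalProfile(latitude=centers, value=smoothed, span=span, season=season)
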