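"""Covariate engineering: cost surfaces, attraction distances, kriging,
and assembly of presence/background sample matrices.

Covariate column names are fixed across the pipeline:
``depth, spawn_attr, winter_attr, temp, oxygen, u_east, v_north``.
Each seasonal model uses exactly one attraction covariate: overwintering
attraction in autumn and winter, spawning attraction in spring and summer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import least_squares
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from .raster import Raster
from .seasons import SEASONS, check_season
from .occurrence import PresenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "COVARIATE_NAMES",
    "ATTRACTION_FOR_SEASON",
    "SphericalVariogram",
    "CovariateStack",
    "SampleMatrix",
    "reclassify_cost",
    "cost_distance",
    "fit_variogram",
    "krige_field",
    "cell_covariates",
    "match_covariates",
    "sample_background",
    "build_samples",
]

COVARIATE_NAMES = ("depth", "spawn_attr", "winter_attr", "temp", "oxygen", "u_east", "v_north")
SEASONAL_NAMES = ("temp", "oxygen", "u_east", "v_north")

#: which attraction covariate each seasonal model is allowed to use
ATTRACTION_FOR_SEASON = {
    "summer": "spawn_attr",
    "spring": "spawn_attr",
    "autumn": "winter_attr",
    "winter": "winter_attr",
}

# depth-class traversal costs: migratory band 10-200 m is cheapest, very
# shallow water intermediate, deeper than 200 m most avoided
_COST_SHALLOW = 5.0
_COST_BAND = 1.0
_COST_DEEP = 10.0


def reclassify_cost(bathymetry: Raster) -> Raster:
    """Three-class traversal-cost surface from positive-down depth (m).

    cost 1 for 10 < depth <= 200, cost 5 for 0 < depth <= 10, cost 10 for
    depth > 200.  Idempotent on repeated application of the depth rule;
    invalid cells stay invalid.
    """
    depth = bathymetry.values
    if np.any((depth <= 0) & bathymetry.valid_mask):
        raise ValueError("non-positive depth inside the valid mask: mask inconsistency")
    cost = np.where(depth > 200.0, _COST_DEEP, np.where(depth > 10.0, _COST_BAND, _COST_SHALLOW))
    return bathymetry.like(cost)


def cost_distance(cost: Raster, attractor: tuple[int, int]) -> Raster:
    """Accumulated least-cost distance from every valid cell to an attractor.

    Movement is 8-connected; a step between adjacent cells costs the mean of
    the two cell costs times the step length (cell_size for rook moves,
    cell_size*sqrt(2) for diagonals).  Unreachable valid cells get +inf and
    are reported with a warning.
    """
    r0, c0 = attractor
    if not (0 <= r0 < cost.n_rows and 0 <= c0 < cost.n_cols) or not cost.valid_mask[r0, c0]:
        raise ValueError(f"attractor cell ({r0}, {c0}) is not on the valid mask")

    valid = cost.valid_mask
    idx = -np.ones(cost.shape, dtype=np.int64)
    rows, cols = np.nonzero(valid)
    idx[rows, cols] = np.arange(rows.size)
    n = rows.size
    cvals = cost.values

    src, dst, wgt = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        length = cost.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < cost.n_rows) & (c2 >= 0) & (c2 < cost.n_cols)
        ok[ok] &= valid[r2[ok], c2[ok]]
        a = idx[rows[ok], cols[ok]]
        b = idx[r2[ok], c2[ok]]
        w = 0.5 * (cvals[rows[ok], cols[ok]] + cvals[r2[ok], c2[ok]]) * length
        src.append(a)
        dst.append(b)
        wgt.append(w)
    graph = sparse.csr_matrix(
        (np.concatenate(wgt), (np.concatenate(src), np.concatenate(dst))), shape=(n, n)
    )
    dist = dijkstra(graph, directed=False, indices=idx[r0, c0])

    unreachable = int(np.isinf(dist).sum())
    if unreachable:
        warnings.warn(f"{unreachable} valid cells unreachable from the attractor", stacklevel=2)
    out = np.full(cost.shape, np.nan)
    out[rows, cols] = dist
    return cost.like(out)


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphericalVariogram:
    """Isotropic spherical variogram: nugget + partial sill rising to range."""

    nugget: float
    psill: float
    range_: float

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        hr = np.clip(h / max(self.range_, 1e-12), 0.0, 1.0)
        gamma = self.nugget + self.psill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h == 0.0, 0.0, gamma)


def fit_variogram(points: np.ndarray, values: np.ndarray, n_bins: int = 12) -> SphericalVariogram:
    """Fit a spherical variogram to binned empirical semivariances by WLS.

    Bins are weighted by their pair counts.  Fitted parameters are logged.
    """
    d = cdist(points, points)
    iu = np.triu_indices(len(points), k=1)
    dists = d[iu]
    semiv = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    hmax = dists.max()
    edges = np.linspace(0.0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dists > lo) & (dists <= hi)
        if sel.sum() >= 1:
            centers.append(dists[sel].mean())
            gammas.append(semiv[sel].mean())
            counts.append(sel.sum())
    h = np.array(centers)
    g = np.array(gammas)
    w = np.sqrt(np.array(counts, dtype=float))
    var = max(values.var(), 1e-12)

    def resid(p):
        return w * (SphericalVariogram(p[0], p[1], p[2])(h) - g)

    p0 = np.array([0.0, max(var, 1e-12), max(hmax / 2.0, 1e-6)])
    sol = least_squares(
        resid, p0, bounds=([0.0, 1e-12, 1e-6], [var * 10 + 1e-9, var * 20 + 1e-6, hmax * 3]),
    )
    vg = SphericalVariogram(*sol.x)
    logger.info("fitted spherical variogram: nugget=%.4g psill=%.4g range=%.4g",
                vg.nugget, vg.psill, vg.range_)
    return vg


def krige_field(
    points: list[tuple[float, float, float]] | np.ndarray,
    target: Raster,
    variogram: SphericalVariogram | None = None,
) -> Raster:
    """Ordinary kriging of scattered point data onto a raster geometry.

    If no variogram is given one is fitted automatically (requires >= 3
    non-collinear points).  A singular kriging system falls back to
    inverse-distance weighting with a warning.  Negative kriging weights are
    logged; with a zero nugget the prediction is exact at data points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (x, y, value) triples")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates and values must be finite")
    xy, vals = pts[:, :2], pts[:, 2]
    n = len(pts)

    if variogram is None:
        if n < 3 or np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
            raise ValueError("variogram fitting needs at least 3 non-collinear points")
        variogram = fit_variogram(xy, vals)
    elif n < 2:
        raise ValueError("kriging needs at least 2 points")

    # ordinary kriging system [[Gamma, 1], [1', 0]] [w; mu] = [gamma0; 1]
    gamma = variogram(cdist(xy, xy))
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = gamma
    A[:n, n] = 1.0
    A[n, :n] = 1.0

    rows, cols = np.nonzero(target.valid_mask)
    centers = np.stack(
        [
            target.origin[0] + (cols + 0.5) * target.cell_size,
            target.origin[1] - (rows + 0.5) * target.cell_size,
        ],
        axis=1,
    )
    d0 = cdist(centers, xy)
    B = np.ones((len(centers), n + 1))
    B[:, :n] = variogram(d0)

    try:
        W = np.linalg.solve(A, B.T)  # (n+1, n_cells)
        preds = W[:n].T @ vals
        n_neg = int((W[:n] < -1e-10).any(axis=0).sum())
        if n_neg:
            logger.info("negative kriging weights at %d of %d cells", n_neg, len(centers))
    except np.linalg.LinAlgError:
        warnings.warn("singular kriging system; falling back to inverse-distance weighting",
                      stacklevel=2)
        w = 1.0 / np.maximum(d0, 1e-9) ** 2
        exact = d0 < 1e-9
        w[exact.any(axis=1)] = exact[exact.any(axis=1)].astype(float)
        preds = (w * vals).sum(axis=1) / w.sum(axis=1)

    out = np.full(target.shape, np.nan)
    out[rows, cols] = preds
    return target.like(out)


# ---------------------------------------------------------------------------
# covariate stack and sample assembly
# ---------------------------------------------------------------------------


@dataclass
class CovariateStack:
    """Aligned covariate layers: static depth/attraction plus seasonal fields.

    ``seasonal`` maps ``(season, year)`` to a dict of the four seasonal
    layers; the key ``(season, None)`` holds the multi-year seasonal
    average.  An optional ``monthly`` dict keyed by ``(year, month)``
    enables month-resolution matching inside the model window.
    """

    depth: Raster
    spawn_attr: Raster
    winter_attr: Raster
    seasonal: dict[tuple[str, int | None], dict[str, Raster]]
    monthly: dict[tuple[int, int], dict[str, Raster]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for layer in (self.spawn_attr, self.winter_attr):
            self.depth.require_same_geometry(layer)
        for key, layers in self.seasonal.items():
            check_season(key[0])
            for name in SEASONAL_NAMES:
                if name not in layers:
                    raise KeyError(f"seasonal layers for {key} missing {name!r}")
                self.depth.require_same_geometry(layers[name])

    def average_over_years(self) -> None:
        """Populate the (season, None) multi-year average layers."""
        for season in SEASONS:
            years = [k for k in self.seasonal if k[0] == season and k[1] is not None]
            if not years:
                continue
            avg = {
                name: self.depth.like(
                    np.mean([self.seasonal[k][name].values for k in years], axis=0)
                )
                for name in SEASONAL_NAMES
            }
            self.seasonal[(season, None)] = avg


@dataclass
class SampleMatrix:
    """Presence-then-background covariate rows for one seasonal model."""

    data: pd.DataFrame  # covariate columns only
    labels: np.ndarray  # 1 presence, 0 background
    season: str

    def __post_init__(self) -> None:
        check_season(self.season)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.data) != len(self.labels):
            raise ValueError("data and labels length mismatch")
        forbidden = {"spawn_attr", "winter_attr"} - {ATTRACTION_FOR_SEASON[self.season]}
        if forbidden & set(self.data.columns):
            raise ValueError(
                f"{self.season} samples must not contain {forbidden} "
                f"(season-restricted attraction rule)"
            )
        if self.data.isna().any().any():
            raise ValueError("sample matrix contains missing covariate values")

    @property
    def covariates(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_presence(self) -> int:
        return int(self.labels.sum())

    def presence_rows(self) -> pd.DataFrame:
        return self.data[self.labels == 1]

    def background_rows(self) -> pd.DataFrame:
        return self.data[self.labels == 0]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.insert(1, "season", self.season)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleMatrix":
        df = pd.read_csv(path)
        season = str(df["season"].iloc[0])
        labels = df.pop("label").to_numpy()
        df = df.drop(columns=["season"])
        return cls(df, labels, season)


def _layers_for(stack: CovariateStack, season: str, year: int | None) -> dict[str, Raster]:
    key = (season, year)
    if key not in stack.seasonal:
        raise KeyError(f"no seasonal layers for season={season!r}, year={year!r}")
    return stack.seasonal[key]


def cell_covariates(
    stack: CovariateStack,
    season: str,
    cells: list[tuple[int, int]],
    year: int | None = None,
    month: int | None = None,
) -> pd.DataFrame:
    """Covariate rows for specific cells under the season's attraction rule."""
    check_season(season)
    rr = np.array([c[0] for c in cells])
    cc = np.array([c[1] for c in cells])
    attr = ATTRACTION_FOR_SEASON[season]
    attr_layer = stack.spawn_attr if attr == "spawn_attr" else stack.winter_attr
    if month is not None and (year, month) in stack.monthly:
        layers = stack.monthly[(year, month)]
    else:
        layers = _layers_for(stack, season, year)
    cols = {
        "depth": stack.depth.values[rr, cc],
        attr: attr_layer.values[rr, cc],
    }
    for name in SEASONAL_NAMES:
        cols[name] = layers[name].values[rr, cc]
    return pd.DataFrame(cols)


def match_covariates(
    records: list[PresenceRecord],
    stack: CovariateStack,
    window_years: tuple[int, int] = (2004, 2006),
    monthly: bool = False,
) -> pd.DataFrame:
    """Attach covariate values to presence records.

    Records whose season-year falls inside ``window_years`` take the layer
    for their own season and year (their own month if ``monthly`` and a
    monthly layer exists); records outside the window take the multi-year
    seasonal average.  The attraction covariate follows the season rule.
    """
    rows = []
    for rec in records:
        in_window = window_years[0] <= rec.year <= window_years[1]
        year = rec.year if in_window else None
        month = rec.month if (monthly and in_window) else None
        row = cell_covariates(stack, rec.season, [(rec.row, rec.col)], year=year, month=month)
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    out = pd.concat(rows, ignore_index=True)
    assert not ({"spawn_attr", "winter_attr"} <= set(out.columns))
    return out


def sample_background(
    stack: CovariateStack, season: str, n: int = 8000, seed: int = 0
) -> pd.DataFrame:
    """Uniform draw of ``n`` distinct valid cells with seasonal-average covariates."""
    from .seasons import rng_for

    check_season(season)
    rows, cols = np.nonzero(stack.depth.valid_mask)
    if n > rows.size:
        raise ValueError(f"requested {n} background points but only {rows.size} valid cells")
    rng = rng_for(seed, f"background:{season}")
    pick = rng.choice(rows.size, size=n, replace=False)
    cells = list(zip(rows[pick].tolist(), cols[pick].tolist()))
    out = cell_covariates(stack, season, cells, year=None)
    out.attrs["cells"] = cells
    return out


def build_samples(
    records: list[PresenceRecord],
    stack: CovariateStack,
    season: str,
    n_background: int = 8000,
    seed: int = 0,
    window_years: tuple[int, int] = (2004, 2006),
    monthly: bool = False,
) -> SampleMatrix:
    """Assemble the presence + background sample matrix for one season."""
    season_records = [r for r in records if r.season == season]
    if not season_records:
        raise ValueError(f"no presence records for season {season!r}")
    pres = match_covariates(season_records, stack, window_years, monthly=monthly)
    bg = sample_background(stack, season, n_background, seed)
    data = pd.concat([pres, bg], ignore_index=True)
    labels = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(len(bg), dtype=int)])
    sm = SampleMatrix(data, labels, season)
    sm.data.attrs["background_cells"] = bg.attrs.get("cells")
    return sm
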