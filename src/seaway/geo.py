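"""Conversion between grid cells and a nominal lon/lat frame.

The synthetic domain lives on a km grid; latitude is an affine function of
row index (carried by a latitude raster) and longitude is mapped from the
x-coordinate by a fixed equirectangular convention.  No projection math.
"""

from __future__ import annotations

import numpy as np

from .raster import Raster

#: reference longitude at x = 0 km
LON0 = -135.0
#: km per degree of longitude (equirectangular, fixed)
KM_PER_DEG = 111.0


def cell_to_lonlat(latitude: Raster, row: int, col: int) -> tuple[float, float]:
    x, _ = latitude.cell_center(row, col)
    return LON0 + x / KM_PER_DEG, float(latitude.values[row, col])


def lonlat_to_cell(latitude: Raster, lon: float, lat: float) -> tuple[int, int]:
    """Nearest grid cell for a lon/lat pair (not necessarily valid)."""
    x = (lon - LON0) * KM_PER_DEG
    col = int(np.clip(round(x / latitude.cell_size - 0.5), 0, latitude.n_cols - 1))
    lat_col = latitude.values[:, col]
    row = int(np.argmin(np.abs(lat_col - lat)))
    return row, col


def cell_distance_km(latitude: Raster, row1: int, col1: int, row2: int, col2: int) -> float:
    """Euclidean distance between two cell centres on the km grid."""
    x1, y1 = latitude.cell_center(row1, col1)
    x2, y2 = latitude.cell_center(row2, col2)
    return float(np.hypot(x2 - x1, y2 - y1))
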