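"""Gridded layers and their plain-text / TIFF serialization.

Every spatial layer in the pipeline is a :class:`Raster`: a uniform grid of
cell-centred values with a validity mask.  Cell coordinates are 0-based
``(row, col)`` with row 0 at the top; ``origin`` is the outer corner of the
top-left cell in kilometres.  All layers participating in one analysis must
share a single geometry (shape, cell size, origin, mask).

Two on-disk formats are supported: ESRI ASCII grid (``.asc``, the canonical
text format) and single-band float GeoTIFF written through :mod:`tifffile`
with ``ModelPixelScale``/``ModelTiepoint`` tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "GeometryError", "read_ascii_grid", "read_geotiff"]

_NODATA = -9999.0


class GeometryError(ValueError):
    """Raised when layers with incompatible grid geometries are combined."""


@dataclass
class Raster:
    """A uniform grid of values over the analysis domain.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_rows, n_cols)``.  Values at invalid
        cells are ignored by all statistics.
    cell_size
        Edge length of one cell in kilometres; must be positive.
    origin
        ``(x, y)`` of the top-left cell's outer corner in kilometres.
    valid_mask
        Boolean array of the same shape; ``True`` marks analysis cells.
        Defaults to all-valid.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise GeometryError("valid_mask shape differs from values shape")

    # -- geometry -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
            and bool(np.array_equal(self.valid_mask, other.valid_mask))
        )

    def require_same_geometry(self, other: "Raster") -> None:
        if not self.same_geometry(other):
            raise GeometryError("rasters do not share a common grid geometry")

    def like(self, values: np.ndarray) -> "Raster":
        """New raster with this geometry and the given values."""
        return Raster(values, self.cell_size, self.origin, self.valid_mask.copy())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] - (row + 0.5) * self.cell_size
        return x, y

    # -- statistics over valid cells ---------------------------------------

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    # -- I/O ----------------------------------------------------------------

    def write_ascii_grid(self, path: str | Path) -> None:
        """Write as ESRI ASCII grid; invalid cells become the nodata value."""
        out = np.where(self.valid_mask, self.values, _NODATA)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1] - self.n_rows * self.cell_size:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {_NODATA:.1f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.8g")

    def write_geotiff(self, path: str | Path) -> None:
        """Write a single-band float32 GeoTIFF (pixel-scale + tiepoint tags)."""
        import tifffile

        out = np.where(self.valid_mask, self.values, np.nan).astype(np.float32)
        scale = (self.cell_size, self.cell_size, 0.0)
        tiepoint = (0.0, 0.0, 0.0, self.origin[0], self.origin[1], 0.0)
        tifffile.imwrite(
            path,
            out,
            extratags=[
                (33550, "d", 3, scale, True),
                (33922, "d", 6, tiepoint, True),
            ],
        )


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid body {values.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA)
    mask = values != nodata
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    vals = np.where(mask, values, np.nan)
    return Raster(vals, cell, origin, mask)


def read_geotiff(path: str | Path) -> Raster:
    """Read a single-band GeoTIFF written by :meth:`Raster.write_geotiff`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags[33550].value if 33550 in tags else (1.0, 1.0, 0.0)
        tie = tags[33922].value if 33922 in tags else (0, 0, 0, 0.0, 0.0, 0.0)
    mask = np.isfinite(values)
    return Raster(values, float(scale[0]), (float(tie[3]), float(tie[4])), mask)
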