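"""Detection-day accounting and seasonal presence aggregation.

Raw acoustic detections become per-month residence time at each hydrophone
("detection days"), which is then collapsed to at most one presence record
per hydrophone per season.  Supplementary month-referenced reports are
merged in after snapping to the analysis grid.

Conventions (documented in the output schema):

* An interval between two consecutive same-site detections is assigned
  wholly to the calendar month containing its start.
* Winter (Dec-Feb) is labelled with the year of its December.
* A single isolated detection accrues zero time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo
from .raster import Raster
from .seasons import check_season, season_year

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionEvent",
    "PresenceRecord",
    "detection_days",
    "aggregate_seasonal",
    "merge_reports",
    "read_detections_csv",
    "write_presence_csv",
    "read_presence_csv",
]


@dataclass(frozen=True)
class DetectionEvent:
    tag_id: str
    hydrophone_id: str
    timestamp: pd.Timestamp


@dataclass(frozen=True)
class PresenceRecord:
    """One occurrence localized in space, season and year."""

    row: int
    col: int
    lon: float
    lat: float
    season: str
    year: int
    source: str = "acoustic"  # 'acoustic' or 'report'
    month: int | None = None

    def __post_init__(self) -> None:
        check_season(self.season)
        if self.source not in ("acoustic", "report"):
            raise ValueError(f"source must be 'acoustic' or 'report', got {self.source!r}")


def _events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    else:
        df = pd.DataFrame(
            {
                "tag_id": [e.tag_id for e in events],
                "hydrophone_id": [e.hydrophone_id for e in events],
                "timestamp": [e.timestamp for e in events],
            }
        )
    return df


def detection_days(events) -> pd.DataFrame:
    """Per-month residence time at each hydrophone from detection gaps.

    For each tag, consecutive detections at the *same* hydrophone with no
    intervening detection elsewhere contribute their elapsed time to that
    hydrophone; the time is assigned to the month containing the interval's
    start.  Returns a table with columns ``tag_id, hydrophone_id, year,
    month, days_present`` (days = summed seconds / 86,400).

    Accepts a list of :class:`DetectionEvent` or an equivalent DataFrame;
    input row order is irrelevant (events are sorted per tag by timestamp).
    """
    df = _events_frame(events)
    cols = ["tag_id", "hydrophone_id", "year", "month", "days_present"]
    if df.empty:
        return pd.DataFrame(columns=cols)

    n0 = len(df)
    df = df.drop_duplicates(subset=["tag_id", "hydrophone_id", "timestamp"])
    if len(df) < n0:
        warnings.warn(f"dropped {n0 - len(df)} duplicate detection rows", stacklevel=2)
    # hydrophone_id as a final sort key keeps the pairing deterministic when
    # two sites report the identical timestamp
    df = df.sort_values(["tag_id", "timestamp", "hydrophone_id"], kind="mergesort").reset_index(
        drop=True
    )

    parts = []
    for tag, grp in df.groupby("tag_id", sort=False):
        if len(grp) < 2:
            logger.debug("tag %s has a single detection; accrues zero time", tag)
            continue
        same = grp["hydrophone_id"].to_numpy()
        ts = grp["timestamp"].to_numpy()
        keep = same[:-1] == same[1:]
        if not keep.any():
            continue
        starts = pd.DatetimeIndex(ts[:-1][keep])
        secs = (ts[1:][keep] - ts[:-1][keep]) / np.timedelta64(1, "s")
        parts.append(
            pd.DataFrame(
                {
                    "tag_id": tag,
                    "hydrophone_id": same[:-1][keep],
                    "year": starts.year,
                    "month": starts.month,
                    "days_present": secs / 86400.0,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=cols)
    out = pd.concat(parts, ignore_index=True)
    out = (
        out.groupby(["tag_id", "hydrophone_id", "year", "month"], as_index=False)["days_present"]
        .sum()
        .sort_values(["tag_id", "hydrophone_id", "year", "month"])
        .reset_index(drop=True)
    )
    return out[cols]


def aggregate_seasonal(
    day_table: pd.DataFrame,
    sites: pd.DataFrame,
    threshold_days: float = 1.0,
    pooled: bool = False,
) -> list[PresenceRecord]:
    """Collapse detection days to one presence record per hydrophone-season.

    A record is emitted for (hydrophone, season, year) when any single tag
    accumulated at least ``threshold_days`` there within the season
    (``pooled=True`` instead sums days over all tags at the site).

    ``sites`` must map every hydrophone_id to row/col/lon/lat.
    """
    site_ix = sites.set_index("hydrophone_id")
    missing = set(day_table["hydrophone_id"]) - set(site_ix.index)
    if missing:
        raise KeyError(f"hydrophone ids missing from site table: {sorted(missing)}")
    if day_table.empty:
        return []

    df = day_table.copy()
    sy = [season_year(m, y) for m, y in zip(df["month"], df["year"])]
    df["season"] = [s for s, _ in sy]
    df["season_year"] = [y for _, y in sy]

    group_keys = ["hydrophone_id", "season", "season_year"]
    if pooled:
        sums = df.groupby(group_keys, as_index=False)["days_present"].sum()
    else:
        per_tag = df.groupby(group_keys + ["tag_id"], as_index=False)["days_present"].sum()
        sums = per_tag.groupby(group_keys, as_index=False)["days_present"].max()

    records = []
    for _, r in sums[sums["days_present"] >= threshold_days].iterrows():
        site = site_ix.loc[r["hydrophone_id"]]
        records.append(
            PresenceRecord(
                row=int(site["row"]),
                col=int(site["col"]),
                lon=float(site["lon"]),
                lat=float(site["lat"]),
                season=r["season"],
                year=int(r["season_year"]),
                source="acoustic",
            )
        )
    records.sort(key=lambda p: (p.year, p.season, p.row, p.col))
    return records


def merge_reports(
    acoustic: list[PresenceRecord],
    reports: list[PresenceRecord],
    latitude: Raster,
    snap_radius_km: float = 10.0,
) -> list[PresenceRecord]:
    """Merge month-referenced supplementary reports into the acoustic records.

    Report locations are snapped to the nearest valid cell; reports farther
    than ``snap_radius_km`` from any valid cell are rejected with a warning.
    Duplicate (cell, season, year) occurrences collapse to a single record,
    acoustic records taking precedence.
    """
    valid_rows, valid_cols = np.nonzero(latitude.valid_mask)
    # valid cell centres and the report position in continuous km coordinates,
    # so off-grid reports measure their true distance (no clipping to the grid)
    cx = latitude.origin[0] + (valid_cols + 0.5) * latitude.cell_size
    cy = latitude.origin[1] - (valid_rows + 0.5) * latitude.cell_size
    lat_col = latitude.values[:, 0]
    dlat_per_row = (lat_col[0] - lat_col[-1]) / max(latitude.n_rows - 1, 1)
    merged: dict[tuple[int, int, str, int], PresenceRecord] = {}
    for rec in acoustic:
        merged.setdefault((rec.row, rec.col, rec.season, rec.year), rec)

    for rec in reports:
        if rec.month is None:
            raise ValueError("report records must carry a collection month")
        season, year = season_year(rec.month, rec.year)
        x = (rec.lon - geo.LON0) * geo.KM_PER_DEG
        row_f = (lat_col[0] - rec.lat) / dlat_per_row
        y = latitude.origin[1] - (row_f + 0.5) * latitude.cell_size
        d_km = np.hypot(cx - x, cy - y)
        i = int(np.argmin(d_km))
        if d_km[i] > snap_radius_km:
            warnings.warn(
                f"report at ({rec.lon:.3f}, {rec.lat:.3f}) is {d_km[i]:.1f} km from the "
                f"nearest valid cell (> {snap_radius_km} km); rejected",
                stacklevel=2,
            )
            continue
        row, col = int(valid_rows[i]), int(valid_cols[i])
        lon, lat = geo.cell_to_lonlat(latitude, row, col)
        snapped = PresenceRecord(
            row=row, col=col, lon=lon, lat=lat,
            season=season, year=year, source="report", month=rec.month,
        )
        merged.setdefault((row, col, season, year), snapped)
    out = list(merged.values())
    out.sort(key=lambda p: (p.year, p.season, p.row, p.col))
    return out


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    return _events_frame(pd.read_csv(path))


def write_presence_csv(records: list[PresenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lon": r.lon, "lat": r.lat, "row": r.row, "col": r.col,
                "season": r.season, "year": r.year, "month": r.month, "source": r.source,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_presence_csv(path: str | Path) -> list[PresenceRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        month = None if pd.isna(r.get("month")) else int(r["month"])
        out.append(
            PresenceRecord(
                row=int(r["row"]), col=int(r["col"]), lon=float(r["lon"]), lat=float(r["lat"]),
                season=str(r["season"]), year=int(r["year"]), source=str(r["source"]), month=month,
            )
        )
    return out
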