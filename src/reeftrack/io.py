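"""Readers/writers for the tabular and raster formats used by the pipeline.

Coordinate and unit conventions
-------------------------------
All analysis happens in a local planar frame of easting/northing metres
(the positioning system's relative X/Y export); no geodetic projection is
performed.  Depth is metres below the sea surface, positive down, as a
pressure sensor reports it; height above bottom is seabed depth minus
sensor depth.  All timestamps are stored and compared in UTC.

Tables are plain :class:`pandas.DataFrame` objects with fixed column names:

* positions  — ``fish_id, t, x, y, depth, hpe`` (``hpe_m`` added after
  calibration).  On disk: ``fish_id, datetime_utc, easting_m, northing_m,
  depth_m, hpe`` with ISO-8601 timestamps.
* stations   — ``station_id, kind, x, y, surveyed`` with ``kind`` in
  ``{"reef", "receiver"}``.
* fates      — ``fish_id, fate, t`` with ``fate`` one of
  :data:`FATE_CLASSES`.

Bathymetry is an ESRI ASCII grid wrapped in :class:`BathymetryGrid`;
meteorology is NDBC standard meteorological text parsed to an hourly
frame.  Downstream modules consume only these containers and never
re-parse text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: Possible end-of-track classifications for a tagged fish.  ``emigration``
#: scores as a departure event in residency analysis; all others censor.
FATE_CLASSES = (
    "predation",
    "emigration",
    "tag_loss",
    "surface_mortality",
    "harvest",
    "unknown",
    "at_large",
)

_POSITION_FILE_COLUMNS = {
    "fish_id": "fish_id",
    "datetime_utc": "t",
    "easting_m": "x",
    "northing_m": "y",
    "depth_m": "depth",
    "hpe": "hpe",
}

# NDBC standard meteorological columns we keep, with their missing-data
# sentinels as documented by the National Data Buoy Center.
_NDBC_FIELDS = {
    "WDIR": ("wind_dir", 999.0),
    "WSPD": ("wind_sustained", 99.0),
    "GST": ("wind_gust", 99.0),
    "WVHT": ("wave_height", 99.0),
    "PRES": ("pressure", 9999.0),
}


# ---------------------------------------------------------------------------
# positions


def read_positions(path: str | Path) -> pd.DataFrame:
    """Read a fish-position table.

    Fixes are grouped by fish and time-sorted; exact duplicate rows (same
    fish, time, x, y) are dropped with a logged count.  ``depth_m`` is
    optional in the file.

    Raises
    ------
    FormatError
        If a mandatory column is missing (the error names it) or a
        timestamp cannot be parsed (the error carries the data line
        number, 1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"fish_id": str})
    mandatory = [c for c in _POSITION_FILE_COLUMNS if c != "depth_m"]
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    if "depth_m" not in df.columns:
        df["depth_m"] = np.nan

    t = pd.to_datetime(df["datetime_utc"], utc=True, errors="coerce", format="ISO8601")
    if t.isna().any():
        line = int(np.flatnonzero(t.isna().to_numpy())[0]) + 1
        raise FormatError(
            f"{path.name}: unparseable timestamp "
            f"{df['datetime_utc'].iloc[line - 1]!r} at data line {line}"
        )
    df = df.rename(columns=_POSITION_FILE_COLUMNS)
    df["t"] = t

    n_raw = len(df)
    df = df.drop_duplicates(subset=["fish_id", "t", "x", "y"])
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("read_positions: dropped %d exact duplicate fixes", n_dropped)

    df = df.sort_values(["fish_id", "t"], kind="mergesort").reset_index(drop=True)
    if (df["hpe"] < 0).any():
        raise FormatError(f"{path.name}: negative hpe values")
    return df[["fish_id", "t", "x", "y", "depth", "hpe"]]


def write_positions(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={v: k for k, v in _POSITION_FILE_COLUMNS.items()})
    out = out[[c for c in _POSITION_FILE_COLUMNS if c in out.columns]]
    out = out.assign(
        datetime_utc=pd.to_datetime(out["datetime_utc"], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stations


def read_stations(path: str | Path) -> pd.DataFrame:
    """Read the station table (reefs and receivers, one coordinate frame)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str, "kind": str})
    for col in ("station_id", "kind", "easting_m", "northing_m", "surveyed"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    bad = set(df["kind"]) - {"reef", "receiver"}
    if bad:
        raise FormatError(f"{path.name}: unknown station kind(s) {sorted(bad)}")
    if df["station_id"].duplicated().any():
        raise FormatError(f"{path.name}: duplicate station_id")
    df = df.rename(columns={"easting_m": "x", "northing_m": "y"})
    df["surveyed"] = df["surveyed"].astype(bool)
    return df[["station_id", "kind", "x", "y", "surveyed"]].reset_index(drop=True)


def write_stations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"x": "easting_m", "y": "northing_m"})
    out[["station_id", "kind", "easting_m", "northing_m", "surveyed"]].to_csv(
        path, index=False
    )


def reefs_only(stations: pd.DataFrame) -> pd.DataFrame:
    """Reef rows of a station table, sorted by id (the tie-break order)."""
    return (
        stations[stations["kind"] == "reef"]
        .sort_values("station_id", kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# bathymetry


@dataclass
class BathymetryGrid:
    """Regular raster of seabed depth (m, positive down).

    ``depth[i, j]`` is row-major from the *north-west* corner (ESRI ASCII
    order): row 0 is the northernmost row.  ``x0, y0`` are the coordinates
    of the lower-left corner of the grid.
    """

    x0: float
    y0: float
    cell: float
    depth: np.ndarray  # (nrows, ncols), NaN where NODATA
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise FormatError("bathymetry cell size must be > 0")
        self.depth = np.asarray(self.depth, dtype=float)

    @property
    def nrows(self) -> int:
        return self.depth.shape[0]

    @property
    def ncols(self) -> int:
        return self.depth.shape[1]

    def depth_at(self, x, y):
        """Seabed depth at the cell containing (x, y); NaN outside / NODATA.

        Nearest-cell lookup, no interpolation: fish-position error at the
        metre scale dominates any within-cell depth gradient.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row_from_s = np.floor((y - self.y0) / self.cell).astype(int)
        row = self.nrows - 1 - row_from_s
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        out[ok] = self.depth[row[ok], col[ok]]
        return out if out.ndim else float(out)


def read_bathymetry(path: str | Path) -> BathymetryGrid:
    """Parse an ESRI ASCII grid of seabed depth (positive down)."""
    path = Path(path)
    header: dict[str, float] = {}
    values: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path.name}: missing header field {key!r}")
    for line in lines[i:]:
        values.extend(float(v) for v in line.split())
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(values) != ncols * nrows:
        raise FormatError(
            f"{path.name}: expected {ncols * nrows} values, found {len(values)}"
        )
    nodata = header.get("nodata_value", -9999.0)
    depth = np.array(values, dtype=float).reshape(nrows, ncols)
    depth[depth == nodata] = np.nan
    return BathymetryGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        depth=depth,
        nodata=nodata,
    )


def write_bathymetry(grid: BathymetryGrid, path: str | Path) -> None:
    depth = np.where(np.isnan(grid.depth), grid.nodata, grid.depth)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x0:.6f}\n")
        fh.write(f"yllcorner {grid.y0:.6f}\n")
        fh.write(f"cellsize {grid.cell:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:.1f}\n")
        for row in depth:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# environment (NDBC standard meteorological text)


def read_environment(path: str | Path) -> pd.DataFrame:
    """Parse NDBC-style standard meteorological text to an hourly frame.

    Returns a frame with column ``t`` (UTC, floored to the hour) plus
    ``wave_height`` (m), ``wind_sustained``/``wind_gust`` (m/s),
    ``wind_dir`` (deg from N) and ``pressure`` (mbar).  Sentinel values
    (99/999/9999) map to missing.  Rows are sorted by hour; duplicate
    hours are averaged.
    """
    path = Path(path)
    names: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split()
                if parts and parts[0] in {"YY", "YYYY"}:
                    names = parts
                continue
            if line.split()[0] in {"YY", "YYYY"}:  # headers without '#'
                names = line.split()
                continue
            rows.append(line.split())
    if not rows:
        raise FormatError(f"{path.name}: no parseable data rows")
    if names is None:
        names = ["YYYY", "MM", "DD", "hh", "mm", "WDIR", "WSPD", "GST", "WVHT",
                 "DPD", "APD", "MWD", "PRES", "ATMP", "WTMP", "DEWP", "VIS",
                 "PTDY", "TIDE"]
    width = min(len(names), min(len(r) for r in rows))
    df = pd.DataFrame([r[:width] for r in rows], columns=names[:width])
    df = df.apply(pd.to_numeric, errors="coerce")

    year = df[names[0]].astype(int)
    if (year < 100).any():  # two-digit years in old NDBC files
        year = year.where(year >= 100, year + 1900)
    try:
        t = pd.to_datetime(
            dict(year=year, month=df["MM"], day=df["DD"], hour=df["hh"]), utc=True
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path.name}: cannot assemble timestamps: {exc}") from exc

    out = pd.DataFrame({"t": t})
    for raw, (name, sentinel) in _NDBC_FIELDS.items():
        if raw in df.columns:
            col = df[raw].astype(float)
            col[col == sentinel] = np.nan
            out[name] = col
        else:
            out[name] = np.nan
    out = out.groupby("t", as_index=False).mean().sort_values("t")
    return out.reset_index(drop=True)


def write_environment(df: pd.DataFrame, path: str | Path) -> None:
    """Write an hourly environment frame in the NDBC text dialect."""
    sentinel_of = {name: sent for _, (name, sent) in _NDBC_FIELDS.items()}
    order = ["wind_dir", "wind_sustained", "wind_gust", "wave_height", "pressure"]
    with open(path, "w") as fh:
        fh.write("#YYYY MM DD hh mm WDIR WSPD GST WVHT PRES\n")
        for _, r in df.iterrows():
            t = pd.Timestamp(r["t"])
            vals = []
            for name in order:
                v = r.get(name, np.nan)
                vals.append(f"{sentinel_of[name]:.1f}" if pd.isna(v) else f"{v:.1f}")
            fh.write(
                f"{t.year} {t.month:02d} {t.day:02d} {t.hour:02d} 00 "
                + " ".join(vals)
                + "\n"
            )


# ---------------------------------------------------------------------------
# fates


def read_fates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"fish_id": str, "fate": str})
    for col in ("fish_id", "fate", "fate_datetime_utc"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    bad = set(df["fate"]) - set(FATE_CLASSES)
    if bad:
        raise FormatError(f"{path.name}: unknown fate class(es) {sorted(bad)}")
    if df["fish_id"].duplicated().any():
        raise FormatError(f"{path.name}: more than one fate record per fish")
    t = pd.to_datetime(df["fate_datetime_utc"], utc=True, errors="coerce")
    if t.isna().any():
        line = int(np.flatnonzero(t.isna().to_numpy())[0]) + 1
        raise FormatError(f"{path.name}: unparseable timestamp at data line {line}")
    return pd.DataFrame({"fish_id": df["fish_id"], "fate": df["fate"], "t": t})


def write_fates(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "fish_id": df["fish_id"],
            "fate": df["fate"],
            "fate_datetime_utc": pd.to_datetime(df["t"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
        }
    )
    out.to_csv(path, index=False)
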