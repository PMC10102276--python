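"""Grid geometry, raster / point-table I/O and format validation.

Coordinates are planar projected meters throughout; CRS metadata, when
present in a GeoTIFF, is carried opaquely and never interpreted.  Grids use
the GeoTIFF convention: origin at the upper-left corner, 0-based row-major
indices, half-open cells.  Missing raster cells are encoded as NaN in
memory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("ippm")

__all__ = [
    "GridSpec",
    "Raster",
    "PointTable",
    "FormatError",
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "POINT_COLUMNS",
]


class FormatError(ValueError):
    """Raised when a file or table violates a structural contract."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an analysis lattice.

    ``(x0, y0)`` is the upper-left corner of the grid; cell ``(i, j)``
    (column, row) covers the half-open box
    ``[x0 + i*dx, x0 + (i+1)*dx) x (y0 - (j+1)*dy, y0 - j*dy]``.
    ``years`` is the inclusive modeled year range.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    nx: int
    ny: int
    years: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise FormatError(f"cell sizes must be positive (dx={self.dx}, dy={self.dy})")
        if not (self.nx >= 1 and self.ny >= 1):
            raise FormatError(f"grid dimensions must be >= 1 (nx={self.nx}, ny={self.ny})")
        y0_, y1_ = self.years
        if y1_ < y0_:
            raise FormatError(f"years must be a non-empty inclusive range, got {self.years}")

    # -- extent ---------------------------------------------------------
    @property
    def x1(self) -> float:
        return self.x0 + self.nx * self.dx

    @property
    def y1(self) -> float:
        """Southern (minimum) northing of the extent."""
        return self.y0 - self.ny * self.dy

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def area(self) -> float:
        return self.nx * self.ny * self.cell_area

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    # -- coordinate helpers --------------------------------------------
    def cell_of(self, x, y):
        """Column/row indices of the cells containing planar points.

        A point on a shared edge belongs to the cell of higher index in x
        and y (half-open box convention).
        """
        i = np.floor((np.asarray(x, dtype=float) - self.x0) / self.dx).astype(int)
        j = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.dy).astype(int)
        # top edge (y == y0) belongs to row 0; left edge to column 0
        j = np.where(np.asarray(y, dtype=float) == self.y0, 0, j)
        return i, j

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x1) & (y > self.y1) & (y <= self.y0)

    def cell_centers(self):
        """(X, Y) arrays of shape (ny, nx) with cell-center coordinates."""
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.dx
        cy = self.y0 - (np.arange(self.ny) + 0.5) * self.dy
        return np.meshgrid(cx, cy)

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.dx, other.dx)
            and np.isclose(self.dy, other.dy)
            and self.nx == other.nx
            and self.ny == other.ny
        )


@dataclass
class Raster:
    """A grid-registered scalar field; NaN marks missing cells."""

    grid: GridSpec
    values: np.ndarray  # shape (ny, nx), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            if self.values.size == self.grid.nx * self.grid.ny:
                self.values = self.values.reshape(self.grid.ny, self.grid.nx)
            else:
                raise FormatError(
                    f"values size {self.values.size} != nx*ny = "
                    f"{self.grid.nx * self.grid.ny}"
                )
        bad = ~np.isfinite(self.values) & ~np.isnan(self.values)
        if bad.any():
            raise FormatError("raster contains non-finite, non-missing values (inf)")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())

    def sample(self, x, y, bilinear: bool = True) -> np.ndarray:
        """Sample values at planar points by bilinear interpolation of
        cell-center values (nearest-cell at a cell center reproduces the
        cell value exactly).  Falls back to nearest cell where a bilinear
        neighbor is missing or outside the grid.
        """
        g = self.grid
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not bilinear:
            i, j = g.cell_of(x, y)
            i = np.clip(i, 0, g.nx - 1)
            j = np.clip(j, 0, g.ny - 1)
            return self.values[j, i]
        # fractional position in cell-center coordinates
        fx = (x - g.x0) / g.dx - 0.5
        fy = (g.y0 - y) / g.dy - 0.5
        i0 = np.clip(np.floor(fx).astype(int), 0, g.nx - 1)
        j0 = np.clip(np.floor(fy).astype(int), 0, g.ny - 1)
        i1 = np.clip(i0 + 1, 0, g.nx - 1)
        j1 = np.clip(j0 + 1, 0, g.ny - 1)
        tx = np.clip(fx - i0, 0.0, 1.0)
        ty = np.clip(fy - j0, 0.0, 1.0)
        v = self.values
        out = (
            v[j0, i0] * (1 - tx) * (1 - ty)
            + v[j0, i1] * tx * (1 - ty)
            + v[j1, i0] * (1 - tx) * ty
            + v[j1, i1] * tx * ty
        )
        # nearest-cell fallback where any corner is missing
        nan_mask = np.isnan(out)
        if np.any(nan_mask):
            i, j = g.cell_of(x, y)
            i = np.clip(i, 0, g.nx - 1)
            j = np.clip(j, 0, g.ny - 1)
            out = np.where(nan_mask, v[j, i], out)
        return out


# ---------------------------------------------------------------------------
# Point tables
# ---------------------------------------------------------------------------

POINT_COLUMNS = [
    "x",
    "y",
    "year",
    "stream",
    "effort_distance",
    "effort_duration",
    "n_observers",
    "start_time",
    "complete",
]

_EFFORT_COLUMNS = ["effort_distance", "effort_duration", "n_observers", "start_time"]
_STREAMS = {"nest", "ebird"}


@dataclass
class PointTable:
    """Presence records for both observation streams.

    Wraps a DataFrame with the canonical columns.  ``effort_*`` fields are
    populated only on ``ebird`` rows; ``nest`` rows carry NaN there.
    ``effort_distance`` is km, ``effort_duration`` hours, ``start_time`` a
    local "HH:MM" clock string.
    """

    df: pd.DataFrame
    grid: GridSpec | None = None
    allow_holdout_years: bool = field(default=False)
    strict_effort: bool = field(default=False)  # reject ebird rows lacking effort

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        for c in POINT_COLUMNS:
            if c not in df.columns:
                if c in ("x", "y", "year", "stream"):
                    raise FormatError(f"point table missing mandatory column '{c}'")
                df[c] = np.nan
        df = df[POINT_COLUMNS]
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        df["year"] = df["year"].astype(int)
        bad_stream = ~df["stream"].isin(_STREAMS)
        if bad_stream.any():
            rows = list(df.index[bad_stream][:5])
            raise FormatError(f"invalid stream value(s) at rows {rows}")
        ebird = df["stream"] == "ebird"
        for c in _EFFORT_COLUMNS:
            present = df[c].notna()
            offending = present & ~ebird
            if offending.any():
                raise FormatError(
                    f"effort column '{c}' set on nest row(s) "
                    f"{list(df.index[offending][:5])}"
                )
            missing = ebird & ~present
            if missing.any() and self.strict_effort:
                raise FormatError(
                    f"ebird row(s) {list(df.index[missing][:5])} lack '{c}'"
                )
        if self.grid is not None:
            inside = self.grid.contains(df["x"].to_numpy(), df["y"].to_numpy())
            if not inside.all():
                rows = list(df.index[~inside][:5])
                raise FormatError(f"point(s) outside grid extent at rows {rows}")
            if not self.allow_holdout_years:
                y0, y1 = self.grid.years
                bad = (df["year"] < y0) | (df["year"] > y1)
                if bad.any():
                    raise FormatError(
                        f"year outside grid range at rows {list(df.index[bad][:5])}"
                    )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "PointTable":
        return PointTable(
            self.df.loc[mask].reset_index(drop=True),
            grid=self.grid,
            allow_holdout_years=self.allow_holdout_years,
        )

    def stream(self, name: str) -> "PointTable":
        return self.subset(self.df["stream"] == name)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.df["x"].to_numpy(), self.df["y"].to_numpy()


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid and GeoTIFF (via tifffile tags)
# ---------------------------------------------------------------------------

_ASC_NODATA = -9999.0


def write_raster(raster: Raster, path) -> str:
    """Write a raster as ESRI ASCII grid (``.asc``/``.txt``) or GeoTIFF."""
    path = str(path)
    if path.lower().endswith((".asc", ".txt", ".grd")):
        _write_ascii(raster, path)
    else:
        _write_gtiff(raster, path)
    return path


def read_raster(path, years: tuple[int, int] = (0, 0), expect: GridSpec | None = None) -> Raster:
    """Read a GeoTIFF or ESRI ASCII grid.

    ``expect`` enforces geometry agreement; mismatch raises a
    :class:`FormatError` naming the offending field.
    """
    path = str(path)
    if path.lower().endswith((".asc", ".txt", ".grd")):
        raster = _read_ascii(path, years)
    else:
        raster = _read_gtiff(path, years)
    if expect is not None:
        got, want = raster.grid, expect
        for name in ("x0", "y0", "dx", "dy", "nx", "ny"):
            a, b = getattr(got, name), getattr(want, name)
            if not np.isclose(a, b):
                raise FormatError(f"raster geometry mismatch in '{name}': {a} != {b}")
        raster = Raster(replace(want), raster.values)
    return raster


def _write_ascii(raster: Raster, path: str) -> None:
    g = raster.grid
    if not np.isclose(g.dx, g.dy):
        raise FormatError("ASCII grid requires square cells (dx == dy)")
    vals = np.where(np.isnan(raster.values), _ASC_NODATA, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.nx}\n")
        fh.write(f"nrows {g.ny}\n")
        fh.write(f"xllcorner {g.x0:.17g}\n")
        fh.write(f"yllcorner {g.y1:.17g}\n")
        fh.write(f"cellsize {g.dx:.17g}\n")
        fh.write(f"NODATA_value {_ASC_NODATA:.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _read_ascii(path: str, years) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                           "nodata_value") and len(parts) == 2:
                    header[key] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
    except (OSError, ValueError) as exc:
        raise FormatError(f"unreadable ASCII grid '{path}': {exc}") from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"ASCII grid '{path}' missing header field '{req}'")
    nx, ny = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    values = np.array([v for r in rows for v in r], dtype=float)
    if values.size != nx * ny:
        raise FormatError(
            f"ASCII grid '{path}': {values.size} cells read, expected nx*ny = {nx * ny}"
        )
    values = values.reshape(ny, nx)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + ny * cs,
        dx=cs,
        dy=cs,
        nx=nx,
        ny=ny,
        years=tuple(years),
    )
    return Raster(grid, values)


# GeoTIFF tag ids (GeoTIFF 1.1 / GDAL conventions)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_gtiff(raster: Raster, path: str) -> None:
    import tifffile

    g = raster.grid
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.dx, g.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x0, g.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, raster.values.astype(np.float64), extratags=extratags)


def _read_gtiff(path: str, years) -> Raster:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray().astype(float)
            scale = page.tags.get(_TAG_PIXEL_SCALE)
            tie = page.tags.get(_TAG_TIEPOINT)
            scale = None if scale is None else tuple(scale.value)
            tie = None if tie is None else tuple(tie.value)
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise FormatError(f"unreadable GeoTIFF '{path}': {exc}") from exc
    if values.ndim != 2:
        raise FormatError(f"GeoTIFF '{path}' is not single-band 2-D")
    ny, nx = values.shape
    if scale is None or tie is None:
        raise FormatError(f"GeoTIFF '{path}' lacks georeferencing tags")
    dx, dy = float(scale[0]), float(scale[1])
    x0, y0 = float(tie[3]), float(tie[4])
    grid = GridSpec(x0=x0, y0=y0, dx=dx, dy=dy, nx=nx, ny=ny, years=tuple(years))
    return Raster(grid, values)


# ---------------------------------------------------------------------------
# Point-table I/O
# ---------------------------------------------------------------------------


def write_points(table: PointTable, path) -> str:
    df = table.df.copy()
    df.to_csv(path, index=False, float_format="%.10g")
    return str(path)


def read_points(path, grid: GridSpec | None = None,
                allow_holdout_years: bool = False) -> PointTable:
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"unreadable point CSV '{path}': {exc}") from exc
    for c in ("x", "y", "year", "stream"):
        if c not in df.columns:
            raise FormatError(f"point CSV '{path}' missing mandatory column '{c}'")
    known = [c for c in POINT_COLUMNS if c in df.columns]
    df = df[known]
    if "complete" in df.columns and df["complete"].notna().any():
        df["complete"] = df["complete"].map(
            lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_))
            else str(v).strip().lower() in ("true", "1", "yes")
        )
    return PointTable(df, grid=grid, allow_holdout_years=allow_holdout_years,
                      strict_effort=True)


def dump_json(obj, path) -> str:
    """Write deterministic JSON (sorted keys, fixed separators)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")
    return str(path)
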