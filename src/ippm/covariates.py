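"""Deterministic covariate-layer transforms, checklist filtering and
design-matrix assembly.

Layer transforms operate on :class:`~ippm.io_core.Raster` objects and
return new rasters on the same grid.  Scale summaries (moving windows) use
cell-center membership: a cell belongs to a radius-``r`` window iff its
center lies within ``r`` of the focal cell center (inclusive); the
``neighbor`` scale is the 8 adjacent cells excluding the focal cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
from shapely.geometry import shape as shapely_shape
from shapely.ops import unary_union

from .io_core import GridSpec, PointTable, Raster

logger = logging.getLogger("ippm")

__all__ = [
    "CovariateSpec",
    "filter_checklists",
    "reclassify_dswe",
    "max_composite",
    "slope_degrees",
    "distance_to",
    "exp_distance",
    "binarize_distance",
    "moving_window",
    "crop_binary",
    "trees_mask",
    "road_density",
    "standardize",
    "Standardizer",
    "correlation_screen",
    "assemble_design",
    "SCALES",
]

SCALES = ("pixel30", "neighbor", "r90", "r150", "r300", "r750")
_RADIUS_M = {"r90": 90.0, "r150": 150.0, "r300": 300.0, "r750": 750.0}


@dataclass(frozen=True)
class CovariateSpec:
    """One candidate covariate: layer, scale, summary statistic, transform."""

    name: str
    source: str
    scale: str = "pixel30"
    stat: str = "mean"
    transform: str = "identity"  # identity | quadratic_pair
    role: str = "ecological"  # ecological | observation
    dynamic: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale '{self.scale}'")
        if self.stat not in ("mean", "sd"):
            raise ValueError(f"unknown stat '{self.stat}'")
        if self.stat == "sd" and self.source not in ("slope",):
            raise ValueError("stat='sd' is only allowed for the slope layer")
        if self.transform not in ("identity", "quadratic_pair"):
            raise ValueError(f"unknown transform '{self.transform}'")

    @property
    def column_names(self) -> list[str]:
        if self.transform == "quadratic_pair":
            return [self.name, f"{self.name}_sq"]
        return [self.name]


# ---------------------------------------------------------------------------
# Checklist filtering
# ---------------------------------------------------------------------------

_T_MIN = 5 * 60  # 05:00, minutes
_T_MAX = 21 * 60  # 21:00


def _parse_minutes(t) -> float:
    if pd.isna(t):
        return np.nan
    hh, mm = str(t).split(":")
    return int(hh) * 60 + int(mm)


def filter_checklists(table: PointTable) -> PointTable:
    """Apply effort-based quality filters to the opportunistic stream.

    Retained ebird rows satisfy all of: distance traveled < 5 km, duration
    < 5 h, at most 10 observers, and a start time between 05:00 and 21:00
    inclusive.  Incomplete checklists are retained (records are
    presence-only).  Nest rows pass through untouched; ebird rows with any
    missing effort field are dropped with a logged count.
    """
    df = table.df
    is_nest = df["stream"] == "nest"
    eb = df[~is_nest]
    if len(eb) == 0:
        return table
    missing = eb[["effort_distance", "effort_duration", "n_observers",
                  "start_time"]].isna().any(axis=1)
    if missing.any():
        logger.info("filter_checklists: dropping %d ebird rows with missing effort",
                    int(missing.sum()))
    minutes = eb["start_time"].map(_parse_minutes)
    keep = (
        ~missing
        & (eb["effort_distance"] < 5.0)
        & (eb["effort_duration"] < 5.0)
        & (eb["n_observers"] <= 10)
        & (minutes >= _T_MIN)
        & (minutes <= _T_MAX)
    )
    mask = is_nest.copy()
    mask.loc[keep.index[keep]] = True
    return table.subset(mask)


# ---------------------------------------------------------------------------
# Layer transforms
# ---------------------------------------------------------------------------


def _check_same_grid(rasters) -> GridSpec:
    g = rasters[0].grid
    for r in rasters[1:]:
        if not g.same_geometry(r.grid):
            raise ValueError("raster sequence has mismatched grid geometry")
    return g


def reclassify_dswe(acquisitions: list[Raster]) -> Raster:
    """Collapse per-acquisition water-confidence codes to binary water.

    A cell is water (1) iff any acquisition codes it 1 (high-confidence
    water); codes 0/2/3/4 never count.  Cells missing in every acquisition
    stay missing.
    """
    g = _check_same_grid(acquisitions)
    stack = np.stack([r.values for r in acquisitions])
    valid = ~np.isnan(stack)
    codes = stack[valid]
    if codes.size and (np.any(codes < 0) | np.any(codes > 4) or
                       not np.allclose(codes, np.round(codes))):
        raise ValueError("DSWE codes must be integers in {0,1,2,3,4}")
    any_water = np.any((stack == 1) & valid, axis=0)
    any_valid = valid.any(axis=0)
    out = np.where(any_water, 1.0, 0.0)
    out[~any_valid] = np.nan
    return Raster(g, out)


def max_composite(rasters: list[Raster]) -> Raster:
    """Cellwise maximum across co-registered rasters, ignoring missing."""
    g = _check_same_grid(rasters)
    stack = np.stack([r.values for r in rasters])
    with np.errstate(all="ignore"):
        out = np.nanmax(stack, axis=0)
    out[np.all(np.isnan(stack), axis=0)] = np.nan
    return Raster(g, out)


def slope_degrees(elevation: Raster) -> Raster:
    """Terrain slope in degrees via Horn's 3x3 weighted central differences."""
    g = elevation.grid
    if not np.isclose(g.dx, g.dy):
        raise ValueError("slope requires square cells (dx == dy)")
    if g.nx < 2 or g.ny < 2:
        raise ValueError("slope undefined on a single-cell raster")
    z = elevation.values
    zp = np.pad(z, 1, mode="edge")
    # Horn kernel: dz/dx weights (1,2,1)/(8 dx) on the flanking columns
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    gg = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + gg)) / (8 * g.dx)
    dzdy = ((gg + 2 * h + i) - (a + 2 * b + c)) / (8 * g.dy)
    out = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out[np.isnan(z)] = np.nan
    return Raster(g, out)


def _feature_mask(features, grid: GridSpec) -> np.ndarray:
    """Boolean (ny, nx) mask of cells touched by vector features or a
    binary raster."""
    if isinstance(features, Raster):
        if not grid.same_geometry(features.grid):
            raise ValueError("feature raster grid mismatch")
        return np.nan_to_num(features.values) > 0
    geoms = []
    for feat in features:
        geoms.append(shapely_shape(feat["geometry"]) if isinstance(feat, dict)
                     else feat)
    if not geoms:
        raise ValueError("empty feature set")
    union = unary_union(geoms)
    X, Y = grid.cell_centers()
    import shapely

    pts = shapely.points(X.ravel(), Y.ravel())
    half_diag = 0.5 * float(np.hypot(grid.dx, grid.dy))
    near = shapely.dwithin(pts, union, half_diag)
    return near.reshape(grid.ny, grid.nx)


def distance_to(features, grid: GridSpec) -> Raster:
    """Exact Euclidean distance (m) from each cell center to the nearest
    feature; 0 on feature cells.

    ``features`` is either a binary raster (cells > 0 are features; distance
    is measured between cell centers) or an iterable of GeoJSON-like
    features / shapely geometries (distance measured to the geometry).
    """
    if isinstance(features, Raster):
        mask = _feature_mask(features, grid)
        if not mask.any():
            raise ValueError("empty feature set: no feature cells on the grid")
        # EDT measures distance to the nearest zero of the input
        dist = scipy.ndimage.distance_transform_edt(
            ~mask, sampling=(grid.dy, grid.dx))
        return Raster(grid, dist)
    import shapely

    geoms = [shapely_shape(f["geometry"]) if isinstance(f, dict) else f
             for f in features]
    if not geoms:
        raise ValueError("empty feature set")
    union = unary_union(geoms)
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(pts, union)
    return Raster(grid, dist.reshape(grid.ny, grid.nx))


def exp_distance(d: Raster, mu: float) -> Raster:
    """Saturating distance kernel ``1 - exp(-d / mu)``, range [0, 1)."""
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    v = d.values
    if np.nanmin(v) < 0:
        raise ValueError("distances must be non-negative")
    return Raster(d.grid, 1.0 - np.exp(-v / mu))


def binarize_distance(d: Raster, threshold: float) -> Raster:
    """1 where distance >= threshold, else 0 (ties map to 1)."""
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out = np.where(d.values >= threshold, 1.0, 0.0)
    out[np.isnan(d.values)] = np.nan
    return Raster(d.grid, out)


def _window_offsets(scale: str, grid: GridSpec) -> np.ndarray:
    """Footprint (boolean 2-D array) of the moving window, focal-centered."""
    if scale == "neighbor":
        fp = np.ones((3, 3), dtype=bool)
        fp[1, 1] = False
        return fp
    radius = _RADIUS_M[scale]
    kx = int(np.floor(radius / grid.dx))
    ky = int(np.floor(radius / grid.dy))
    ox = np.arange(-kx, kx + 1) * grid.dx
    oy = np.arange(-ky, ky + 1) * grid.dy
    OX, OY = np.meshgrid(ox, oy)
    return np.hypot(OX, OY) <= radius + 1e-9


def moving_window(raster: Raster, scale: str, stat: str = "mean") -> Raster:
    """Per-cell window statistic; missing cells are excluded from the
    statistic, and a window with no valid cells yields missing."""
    if scale == "pixel30":
        return raster.copy()
    if scale not in SCALES:
        raise ValueError(f"unknown scale '{scale}'")
    if stat not in ("mean", "sd"):
        raise ValueError(f"unknown stat '{stat}'")
    fp = _window_offsets(scale, raster.grid)
    v = raster.values
    valid = (~np.isnan(v)).astype(float)
    vz = np.nan_to_num(v)
    # correlate with edge-truncation: pad with zeros and count valid cells
    ksum = scipy.ndimage.correlate(vz, fp.astype(float), mode="constant", cval=0.0)
    kcnt = scipy.ndimage.correlate(valid, fp.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = ksum / kcnt
        if stat == "mean":
            out = mean
        else:
            ksq = scipy.ndimage.correlate(vz**2, fp.astype(float),
                                          mode="constant", cval=0.0)
            var = ksq / kcnt - mean**2
            # guard tiny negative round-off and undefined single-cell sd
            var = np.where(kcnt >= 2, np.maximum(var, 0.0) * kcnt / (kcnt - 1),
                           np.nan)
            out = np.sqrt(var)
    out[kcnt == 0] = np.nan
    return Raster(raster.grid, out)


def crop_binary(landcover: Raster, crop_codes=(81, 82)) -> Raster:
    """1 for pasture/hay or cultivated-crop cells, 0 otherwise.

    Default codes follow the NLCD convention (81 pasture/hay,
    82 cultivated crops); a custom code table may be supplied.
    """
    return _code_mask(landcover, crop_codes)


def trees_mask(landcover: Raster, tree_codes=(41, 42, 43)) -> Raster:
    """1 for deciduous / evergreen / mixed forest cells, 0 otherwise."""
    return _code_mask(landcover, tree_codes)


_NLCD_CODES = {11, 12, 21, 22, 23, 24, 31, 41, 42, 43, 51, 52, 71, 72, 73, 74,
               81, 82, 90, 95}


def _code_mask(landcover: Raster, codes, known=_NLCD_CODES) -> Raster:
    v = landcover.values
    vv = v[~np.isnan(v)]
    unknown = set(np.unique(vv).astype(int)) - set(known) - set(int(c) for c in codes)
    if unknown:
        raise ValueError(f"unknown landcover code(s): {sorted(unknown)}")
    out = np.isin(v, list(codes)).astype(float)
    out[np.isnan(v)] = np.nan
    return Raster(landcover.grid, out)


def road_density(roads, grid: GridSpec, radius: float = 5000.0) -> Raster:
    """Road length (km) within ``radius`` m of each cell center, divided by
    the disc area (km^2)."""
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    geoms = []
    for feat in roads:
        geoms.append(shapely_shape(feat["geometry"]) if isinstance(feat, dict)
                     else feat)
    X, Y = grid.cell_centers()
    out = np.zeros(grid.n_cells)
    disc_area_km2 = np.pi * (radius / 1000.0) ** 2
    if geoms:
        import shapely

        union = unary_union(geoms)
        pts = shapely.points(X.ravel(), Y.ravel())
        discs = shapely.buffer(pts, radius, quad_segs=16)
        clipped = shapely.intersection(discs, union)
        out = shapely.length(clipped) / 1000.0 / disc_area_km2
    return Raster(grid, out.reshape(grid.ny, grid.nx))


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Per-column (mean, sd) computed on a reference point set and reapplied
    verbatim at prediction time.  Sample (n-1) standard deviation."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @classmethod
    def fit(cls, design: pd.DataFrame, allow_constant: bool = False) -> "Standardizer":
        s = cls()
        for c in design.columns:
            col = design[c].to_numpy(dtype=float)
            m = float(np.mean(col))
            sd = float(np.std(col, ddof=1))
            if sd <= 0 or not np.isfinite(sd):
                if not allow_constant:
                    raise ValueError(
                        f"covariate '{c}' has zero variance; cannot standardize")
                sd = 1.0  # centered constant contributes nothing downstream
            s.means[c] = m
            s.sds[c] = sd
        return s

    def transform(self, design: pd.DataFrame) -> pd.DataFrame:
        out = design.copy()
        for c in design.columns:
            if c not in self.means:
                raise KeyError(f"no stored scaling for column '{c}'")
            out[c] = (design[c] - self.means[c]) / self.sds[c]
        return out

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


def standardize(design: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Center/scale each column to mean 0, sd 1 (sample sd) and return the
    fitted scaler for later reuse."""
    scaler = Standardizer.fit(design)
    return scaler.transform(design), scaler


def correlation_screen(design: pd.DataFrame, threshold: float = 0.70) -> pd.DataFrame:
    """Report column pairs with Pearson |r| above threshold.

    Quadratic partners (``name`` vs ``name_sq``) are exempt: the pair is
    definitionally related.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        return pd.DataFrame(columns=["a", "b", "r"])
    corr = design.corr(method="pearson")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if b == f"{a}_sq" or a == f"{b}_sq":
                continue
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                rows.append({"a": a, "b": b, "r": float(r)})
    return pd.DataFrame(rows, columns=["a", "b", "r"])


class LayerSet(dict):
    """Mapping from layer name to Raster or, for dynamic layers, a
    ``{year: Raster}`` mapping."""

    def layer_for(self, name: str, year: int) -> Raster:
        if name not in self:
            raise KeyError(f"missing layer '{name}'")
        entry = self[name]
        if isinstance(entry, Raster):
            return entry
        if year not in entry:
            raise KeyError(f"missing layer '{name}' for year {year}")
        return entry[year]


def _scaled_layer(layers: LayerSet, spec: CovariateSpec, year: int,
                  cache: dict | None = None) -> Raster:
    key = (spec.source, spec.scale, spec.stat, year if spec.dynamic else None)
    if cache is not None and key in cache:
        return cache[key]
    base = layers.layer_for(spec.source, year)
    out = moving_window(base, spec.scale, spec.stat)
    if cache is not None:
        cache[key] = out
    return out


def assemble_design(points, layers, specs: list[CovariateSpec],
                    year: int | None = None, cache: dict | None = None,
                    bilinear: bool = True) -> pd.DataFrame:
    """Build the design matrix for point locations or a full grid.

    ``points`` is either a DataFrame with x/y (and optionally ``year``)
    columns, or a :class:`GridSpec` (per-cell design for one year).  Values
    at points are bilinear samples of cell-center values; quadratic pairs
    expand into two columns (the square taken after scale summarization,
    before standardization).
    """
    if not isinstance(layers, LayerSet):
        layers = LayerSet(layers)
    if isinstance(points, GridSpec):
        grid = points
        if year is None:
            raise ValueError("grid designs require an explicit year")
        data = {}
        for spec in sorted(specs, key=lambda s: s.name):
            lay = _scaled_layer(layers, spec, year, cache)
            col = lay.values.ravel()
            data[spec.name] = col
            if spec.transform == "quadratic_pair":
                data[f"{spec.name}_sq"] = col**2
        return pd.DataFrame(data)
    df = points.df if isinstance(points, PointTable) else points
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    yrs = df["year"].to_numpy() if "year" in df else np.full(len(df), year)
    data = {}
    for spec in sorted(specs, key=lambda s: s.name):
        vals = np.empty(len(df))
        if spec.dynamic:
            for yr in np.unique(yrs):
                m = yrs == yr
                lay = _scaled_layer(layers, spec, int(yr), cache)
                vals[m] = lay.sample(x[m], y[m], bilinear=bilinear)
        else:
            lay = _scaled_layer(layers, spec, int(yrs[0]) if len(yrs) else 0, cache)
            vals = lay.sample(x, y, bilinear=bilinear)
        data[spec.name] = vals
        if spec.transform == "quadratic_pair":
            data[f"{spec.name}_sq"] = vals**2
    out = pd.DataFrame(data)
    n_missing = int(out.isna().any(axis=1).sum())
    if n_missing:
        logger.info("assemble_design: %d rows contain missing covariates", n_missing)
    return out
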