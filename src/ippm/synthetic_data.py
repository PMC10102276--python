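"""Seeded synthetic landscapes, latent fields and point streams.

Everything downstream of raw-imagery processing is testable against this
module: it generates static and per-year dynamic covariate layers with
spatial (and temporal) autocorrelation, vector features (lakes, roads,
settlements, trees) with exact distance layers, a Matern x AR1 latent
field, and the two presence streams - structured points from the latent
intensity and opportunistic points from a thinned intensity.

Point placement is exact for the piecewise-constant intensity used
throughout: per-cell Poisson counts with uniform jitter inside the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from . import covariates as cov
from . import random_field as rf
from .io_core import GridSpec, PointTable, Raster

__all__ = ["TruthSpec", "make_landscape", "sample_field", "simulate_points",
           "default_truth", "simulate_world"]

_ETA_CAP = 30.0


@dataclass
class TruthSpec:
    """Generative ground truth for recovery tests.

    ``beta``/``delta`` are on the standardized-covariate log-intensity
    scale; ``scaler`` records the grid-cell standardization they refer to.
    ``intercepts['nest']`` is log intensity per m^2; ``intercepts['ebird']``
    is the log thinning offset (kept <= 0 so the clamp at 1 is inactive in
    the default recipes).
    """

    grid: GridSpec
    field: rf.FieldParams
    beta: dict[str, float]
    delta: dict[str, float]
    intercepts: dict[str, float]
    eco_specs: list = dc_field(default_factory=list)
    obs_specs: list = dc_field(default_factory=list)
    scaler: cov.Standardizer | None = None
    effort_config: dict = dc_field(default_factory=lambda: {
        "distance_logmean": 0.0, "distance_logsd": 0.5,   # km, lognormal
        "duration_logmean": 0.0, "duration_logsd": 0.5,   # hours
        "observers_mean": 1.5,
        "complete_prob": 0.8,
    })

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "delta": self.delta,
            "intercepts": self.intercepts,
            "field": {"rho": self.field.rho, "sigma": self.field.sigma,
                      "phi": self.field.phi},
            "grid": {"x0": self.grid.x0, "y0": self.grid.y0,
                     "dx": self.grid.dx, "dy": self.grid.dy,
                     "nx": self.grid.nx, "ny": self.grid.ny,
                     "years": list(self.grid.years)},
            "scaler": self.scaler.to_dict() if self.scaler else None,
        }


def _smooth_layer(grid: GridSpec, rho_cells: float, rng: np.random.Generator,
                  n_years: int = 0, phi: float = 0.7) -> np.ndarray:
    """Unit-variance smooth random surface(s) via the lattice GMRF."""
    rho = max(rho_cells * grid.dx, 2 * grid.dx)
    sp = rf.spatial_precision(grid, rho=rho, sigma=1.0)
    if n_years == 0:
        return sp.sample(rng).reshape(grid.ny, grid.nx)
    st = rf.spacetime_precision(sp, phi, n_years)
    return st.sample(rng).reshape(n_years, grid.ny, grid.nx)


def _random_lakes(grid: GridSpec, rng: np.random.Generator, n: int):
    lakes = []
    span = min(grid.x1 - grid.x0, grid.y0 - grid.y1)
    for _ in range(n):
        cx = grid.x0 + rng.uniform(0.15, 0.85) * (grid.x1 - grid.x0)
        cy = grid.y1 + rng.uniform(0.15, 0.85) * (grid.y0 - grid.y1)
        r = rng.uniform(0.03, 0.10) * span
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        wob = 1.0 + 0.25 * rng.standard_normal(theta.size)
        ring = [(cx + r * w * np.cos(t), cy + r * w * np.sin(t))
                for t, w in zip(theta, wob)]
        lakes.append(Polygon(ring).buffer(0))
    return lakes


def _random_roads(grid: GridSpec, rng: np.random.Generator, n: int):
    roads = []
    for _ in range(n):
        if rng.random() < 0.5:  # roughly east-west
            y_a = grid.y1 + rng.random() * (grid.y0 - grid.y1)
            y_b = grid.y1 + rng.random() * (grid.y0 - grid.y1)
            roads.append(LineString([(grid.x0, y_a), (grid.x1, y_b)]))
        else:
            x_a = grid.x0 + rng.random() * (grid.x1 - grid.x0)
            x_b = grid.x0 + rng.random() * (grid.x1 - grid.x0)
            roads.append(LineString([(x_a, grid.y1), (x_b, grid.y0)]))
    return roads


def make_landscape(grid: GridSpec, seed: int, n_lakes: int = 3, n_roads: int = 4,
                   n_settlements: int = 3, road_density_radius: float | None = None,
                   flat: bool = False):
    """Generate the full synthetic layer set.

    Returns ``(layers, features)`` where ``layers`` is a
    :class:`~ippm.covariates.LayerSet` holding the static layers (slope,
    dist_lake, dist_trees, dist_roads, dist_settlements, road_density,
    crop) and per-year dynamic layers (percent_water, ndvi), and
    ``features`` maps feature kind to shapely geometries.
    """
    rng = np.random.default_rng(seed)
    years = grid.year_list
    span = min(grid.x1 - grid.x0, grid.y0 - grid.y1)
    if road_density_radius is None:
        road_density_radius = max(span / 6.0, 3 * grid.dx)

    # topography
    if flat:
        elev = np.zeros((grid.ny, grid.nx))
    else:
        elev = 50.0 * _smooth_layer(grid, 10.0, rng)
    elevation = Raster(grid, elev)
    slope = cov.slope_degrees(elevation)

    # vector features and exact distance layers
    lakes = _random_lakes(grid, rng, n_lakes)
    roads = _random_roads(grid, rng, n_roads)
    settlements = [Point(grid.x0 + rng.random() * (grid.x1 - grid.x0),
                         grid.y1 + rng.random() * (grid.y0 - grid.y1))
                   for _ in range(n_settlements)]
    dist_lake = cov.distance_to(lakes, grid)
    dist_roads = cov.distance_to(roads, grid)
    dist_settlements = cov.distance_to(settlements, grid)
    rdens = cov.road_density(roads, grid, radius=road_density_radius)

    # land cover: trees and crop from thresholded smooth surfaces
    tree_surface = _smooth_layer(grid, 6.0, rng)
    trees = Raster(grid, (tree_surface > np.quantile(tree_surface, 0.85)).astype(float))
    if not trees.values.any():
        trees.values[0, 0] = 1.0
    dist_trees = cov.distance_to(trees, grid)
    crop_surface = _smooth_layer(grid, 8.0, rng)
    crop = Raster(grid, (crop_surface > np.quantile(crop_surface, 0.6)).astype(float))

    # dynamic layers with AR1 persistence across years
    water = _smooth_layer(grid, 6.0, rng, n_years=len(years), phi=0.7)
    ndvi = _smooth_layer(grid, 8.0, rng, n_years=len(years), phi=0.7)
    pct_water = {}
    ndvi_layers = {}
    for k, yr in enumerate(years):
        w = 100.0 / (1.0 + np.exp(-(water[k] - 1.0)))  # mostly dry, in [0, 100]
        pct_water[yr] = Raster(grid, w)
        ndvi_layers[yr] = Raster(grid, np.clip(0.35 + 0.25 * ndvi[k], -1.0, 1.0))

    # spatial surfaces of typical local checklist effort (observation design;
    # independent smooth fields, hence near-orthogonal to the ecology layers)
    eff_d = _smooth_layer(grid, 7.0, rng)
    eff_t = _smooth_layer(grid, 9.0, rng)
    effort_distance = Raster(grid, np.exp(0.0 + 0.4 * eff_d))  # km, lognormal-ish
    effort_duration = Raster(grid, np.exp(0.0 + 0.4 * eff_t))  # hours

    layers = cov.LayerSet({
        "elevation": elevation,
        "slope": slope,
        "dist_lake": dist_lake,
        "dist_trees": dist_trees,
        "dist_roads": dist_roads,
        "dist_settlements": dist_settlements,
        "road_density": rdens,
        "crop": crop,
        "trees": trees,
        "percent_water": pct_water,
        "ndvi": ndvi_layers,
        "effort_distance": effort_distance,
        "effort_duration": effort_duration,
    })
    features = {"lakes": lakes, "roads": roads, "settlements": settlements}
    return layers, features


def sample_field(params: rf.FieldParams, grid: GridSpec, seed: int,
                 coarsen: int = 1) -> dict[int, Raster]:
    """Draw one realization of the Matern x AR1 field, one raster per year.

    With ``coarsen > 1`` the field is drawn on a coarsened lattice and
    replicated to the data grid (piecewise constant), mirroring the
    resolution decoupling used by the estimator.
    """
    if coarsen > 1:
        nxc = int(np.ceil(grid.nx / coarsen))
        nyc = int(np.ceil(grid.ny / coarsen))
        cgrid = GridSpec(x0=grid.x0, y0=grid.y0, dx=grid.dx * coarsen,
                         dy=grid.dy * coarsen, nx=nxc, ny=nyc, years=grid.years)
    else:
        cgrid = grid
    sp = rf.spatial_precision(cgrid, rho=params.rho, sigma=params.sigma)
    st = rf.spacetime_precision(sp, params.phi, grid.n_years)
    u = st.sample(np.random.default_rng(seed)).reshape(
        grid.n_years, cgrid.ny, cgrid.nx)
    if coarsen > 1:
        ry = np.clip(np.arange(grid.ny) // coarsen, 0, cgrid.ny - 1)
        rx = np.clip(np.arange(grid.nx) // coarsen, 0, cgrid.nx - 1)
        u = u[:, ry[:, None], rx[None, :]]
    return {yr: Raster(grid, u[k]) for k, yr in enumerate(grid.year_list)}


def default_truth(grid: GridSpec, layers, field_params: rf.FieldParams | None = None,
                  target_nests: float = 2000.0, target_ebird: float = 300.0) -> TruthSpec:
    """Default generative coefficients.

    Signs and rough magnitudes follow the regime of interest: strong
    water/lake effects with a quadratic water term, negative slope and crop
    effects, and positive road-density / effort thinning coefficients on
    the opportunistic stream.  Intercepts are calibrated so the expected
    total counts (over field realizations) hit the requested targets.
    """
    eco_specs = [
        cov.CovariateSpec("percent_water", "percent_water", scale="r90",
                          transform="quadratic_pair", dynamic=True),
        cov.CovariateSpec("ndvi", "ndvi", dynamic=True),
        cov.CovariateSpec("slope", "slope"),
        cov.CovariateSpec("crop", "crop", scale="neighbor"),
        cov.CovariateSpec("lake_exp", "lake_exp"),
    ]
    obs_specs = [
        cov.CovariateSpec("road_density", "road_density", role="observation"),
        cov.CovariateSpec("effort_distance", "effort_distance", role="observation"),
        cov.CovariateSpec("effort_duration", "effort_duration", role="observation"),
    ]
    beta = {
        "percent_water": 1.1,
        "percent_water_sq": -0.4,
        "ndvi": 0.1,
        "slope": -0.4,
        "crop": -0.5,
        "lake_exp": -1.5,
    }
    delta = {"road_density": 0.5, "effort_distance": 0.3, "effort_duration": 0.2}
    if field_params is None:
        field_params = rf.FieldParams(rho=8 * grid.dx, sigma=0.8, phi=0.8)
    truth = TruthSpec(
        grid=grid, field=field_params, beta=beta, delta=delta,
        intercepts={"nest": 0.0, "ebird": 0.0},
        eco_specs=eco_specs, obs_specs=obs_specs,
    )
    calibrate_intercepts(truth, layers, target_nests, target_ebird)
    return truth


def calibrate_intercepts(truth: TruthSpec, layers, target_nests: float,
                         target_ebird: float) -> None:
    """Set the stream intercepts so expected total counts (averaged over
    field realizations, lognormal correction sigma^2/2) match the targets."""
    grid = truth.grid
    cache: dict = {}
    designs = {yr: _grid_design(truth, layers, yr, cache) for yr in grid.year_list}
    if truth.scaler is None:
        pooled = pd.concat(designs.values(), ignore_index=True)
        truth.scaler = cov.Standardizer.fit(pooled, allow_constant=True)
    xb = []
    for yr in grid.year_list:
        d = truth.scaler.transform(designs[yr])
        eta = np.zeros(grid.n_cells)
        for name, b in truth.beta.items():
            eta += b * d[name].to_numpy()
        xb.append(eta)
    xb = np.concatenate(xb)
    log_correction = truth.field.sigma**2 / 2.0
    denom = float(np.exp(xb).sum()) * grid.cell_area
    if target_nests > 0:
        truth.intercepts["nest"] = float(
            np.log(target_nests) - np.log(denom) - log_correction)
    if target_ebird and truth.obs_specs:
        obs_design = cov.assemble_design(grid, layers, truth.obs_specs,
                                         year=grid.year_list[0])
        obs_scaled, _ = cov.standardize(obs_design)
        dz = np.zeros(grid.n_cells)
        for name in obs_scaled.columns:
            if name in truth.delta:
                dz += truth.delta[name] * obs_scaled[name].to_numpy()
        lam = np.exp(xb + truth.intercepts["nest"] + log_correction) \
            * grid.cell_area
        dz_t = np.tile(dz, grid.n_years)

        def expected(d0):
            return float((lam * np.minimum(np.exp(d0 + dz_t), 1.0)).sum())

        lo, hi = -20.0, 5.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if expected(mid) < target_ebird:
                lo = mid
            else:
                hi = mid
        truth.intercepts["ebird"] = 0.5 * (lo + hi)


def _grid_design(truth: TruthSpec, layers, year: int, cache: dict) -> pd.DataFrame:
    lay = dict(layers)
    if "lake_exp" in truth.beta and "lake_exp" not in lay:
        d = lay["dist_lake"]
        mu = max(float(np.mean(d.values)), 1e-9)
        lay["lake_exp"] = cov.exp_distance(d, mu)
    return cov.assemble_design(truth.grid, cov.LayerSet(lay), truth.eco_specs,
                               year=year, cache=cache)


def log_intensity(truth: TruthSpec, layers, field: dict[int, Raster]):
    """Per-year log intensity surface eta(s, t) = b0 + X beta + u, on the
    per-m^2 scale.  Fits the grid-cell standardizer on first use."""
    grid = truth.grid
    cache: dict = {}
    designs = {yr: _grid_design(truth, layers, yr, cache) for yr in grid.year_list}
    if truth.scaler is None:
        pooled = pd.concat(designs.values(), ignore_index=True)
        truth.scaler = cov.Standardizer.fit(pooled, allow_constant=True)
    etas = {}
    for yr in grid.year_list:
        d = truth.scaler.transform(designs[yr])
        eta = np.full(grid.n_cells, truth.intercepts["nest"])
        for name, b in truth.beta.items():
            eta += b * d[name].to_numpy()
        eta += field[yr].values.ravel()
        etas[yr] = Raster(grid, eta.reshape(grid.ny, grid.nx))
    return etas


def _draw_points_from_rate(rate: np.ndarray, grid: GridSpec, year: int,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell Poisson counts (mean = rate, per cell) with uniform jitter."""
    counts = rng.poisson(rate.ravel())
    idx = np.repeat(np.arange(grid.n_cells), counts)
    n = len(idx)
    i = idx % grid.nx
    j = idx // grid.nx
    x = grid.x0 + (i + rng.random(n)) * grid.dx
    y = grid.y0 - (j + rng.random(n)) * grid.dy
    return pd.DataFrame({"x": x, "y": y, "year": year})


def thinning_surface(truth: TruthSpec, layers) -> tuple[np.ndarray, cov.Standardizer]:
    """Spatial log-thinning surface log b(s) (clamped at 0 so b <= 1) and
    the grid-cell standardizer used for the observation design."""
    grid = truth.grid
    obs_design = cov.assemble_design(grid, layers, truth.obs_specs,
                                     year=grid.year_list[0])
    obs_scaled, obs_scaler = cov.standardize(obs_design)
    log_b = np.full(grid.n_cells, truth.intercepts["ebird"])
    for name in obs_scaled.columns:
        if name in truth.delta:
            log_b += truth.delta[name] * obs_scaled[name].to_numpy()
    return np.minimum(log_b, 0.0), obs_scaler


def simulate_points(truth: TruthSpec, layers, field: dict[int, Raster],
                    seed: int, eta_cap: float = _ETA_CAP) -> PointTable:
    """Draw both presence streams from the generative model.

    The nest stream is Poisson with per-cell mean ``exp(eta) * cell_area``;
    the opportunistic stream uses intensity ``lambda(s, t) * b(s)`` with
    ``log b = d0 + delta . Z_std(s)`` clamped at ``b <= 1``, where Z holds
    the spatial accessibility/effort surfaces.  Recorded per-checklist
    effort metadata are the local surface values perturbed by lognormal
    noise (the checklist filters act on these recorded values).
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    etas = log_intensity(truth, layers, field)
    ec = truth.effort_config
    log_b, obs_scaler = thinning_surface(truth, layers)

    eff_d = layers.layer_for("effort_distance", grid.year_list[0]) \
        if "effort_distance" in layers else None
    eff_t = layers.layer_for("effort_duration", grid.year_list[0]) \
        if "effort_duration" in layers else None

    frames = []
    for yr in grid.year_list:
        eta = etas[yr].values.ravel()
        if np.nanmax(eta) > eta_cap:
            raise ValueError(
                f"log intensity exceeds cap ({np.nanmax(eta):.2f} > {eta_cap}); "
                "rescale the truth coefficients")
        lam_cell = np.exp(eta) * grid.cell_area
        nests = _draw_points_from_rate(lam_cell, grid, yr, rng)
        nests["stream"] = "nest"
        frames.append(nests)

        cand = _draw_points_from_rate(lam_cell * np.exp(log_b), grid, yr, rng)
        m = len(cand)
        if m:
            cand["stream"] = "ebird"
            x, y = cand["x"].to_numpy(), cand["y"].to_numpy()
            base_d = eff_d.sample(x, y) if eff_d is not None else np.ones(m)
            base_t = eff_t.sample(x, y) if eff_t is not None else np.ones(m)
            noise_d = np.exp(rng.normal(0.0, ec["distance_logsd"] * 0.3, m))
            noise_t = np.exp(rng.normal(0.0, ec["duration_logsd"] * 0.3, m))
            cand["effort_distance"] = np.minimum(base_d * noise_d, 4.99)
            cand["effort_duration"] = np.minimum(base_t * noise_t, 4.99)
            cand["n_observers"] = 1 + rng.poisson(ec["observers_mean"] - 1.0, m)
            minutes = rng.integers(5 * 60, 21 * 60 + 1, m)
            cand["start_time"] = [f"{mm // 60:02d}:{mm % 60:02d}" for mm in minutes]
            cand["complete"] = rng.random(m) < ec["complete_prob"]
            frames.append(cand)
    df = pd.concat(frames, ignore_index=True)
    table = PointTable(df, grid=grid)
    table.obs_scaler = obs_scaler  # reference scaling for delta recovery
    return table


def simulate_world(grid: GridSpec, seed: int, truth: TruthSpec | None = None,
                   target_nests: float = 2000.0, target_ebird: float = 300.0,
                   field_coarsen: int = 1, calibrate_on_field: bool = True,
                   **landscape_kw):
    """One-call world: landscape + field + points.  Returns a dict.

    ``calibrate_on_field`` recenters the nest intercept on the realized
    field draw so the expected total count equals ``target_nests`` exactly
    (rather than only in expectation over field realizations).
    """
    layers, features = make_landscape(grid, seed, **landscape_kw)
    if truth is None:
        truth = default_truth(grid, layers, target_nests=target_nests,
                              target_ebird=target_ebird)
    field = sample_field(truth.field, grid, seed + 1, coarsen=field_coarsen)
    if calibrate_on_field and target_nests:
        etas = log_intensity(truth, layers, field)
        total = sum(float(np.exp(e.values).sum()) for e in etas.values()) \
            * grid.cell_area
        truth.intercepts["nest"] += float(np.log(target_nests) - np.log(total))
    points = simulate_points(truth, layers, field, seed + 2)
    if "lake_exp" in truth.beta and "lake_exp" not in layers:
        d = layers["dist_lake"]
        mu = max(float(np.mean(d.values)), 1e-9)
        layers["lake_exp"] = cov.exp_distance(d, mu)
    return {"layers": layers, "features": features, "truth": truth,
            "field": field, "points": points}
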