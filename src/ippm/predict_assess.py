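"""Annual intensity prediction, skill-score thresholding, and abundance
indices with bootstrap intervals."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import covariates as cov
from .io_core import Raster

logger = logging.getLogger("ippm")

__all__ = [
    "PredictionSurface",
    "ConfusionRates",
    "predict",
    "sedi",
    "select_threshold",
    "abundance",
    "abundance_ci",
    "aggregate_normalize",
]

_EPS = 1e-6


@dataclass
class PredictionSurface:
    """Predicted intensity for one year (expected points per cell)."""

    year: int
    lam: Raster
    field_mode: str  # "year_specific" | "averaged"
    tau: float | None = None
    suitability: Raster | None = None

    def apply_threshold(self, tau: float) -> "PredictionSurface":
        suit = np.where(self.lam.values > tau, 1.0, 0.0)
        suit[np.isnan(self.lam.values)] = np.nan
        return PredictionSurface(self.year, self.lam, self.field_mode,
                                 tau=tau, suitability=Raster(self.lam.grid, suit))


@dataclass(frozen=True)
class ConfusionRates:
    """Hit rate H and false-alarm rate F of a binary classification."""

    H: float
    F: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.H <= 1.0 and 0.0 <= self.F <= 1.0):
            raise ValueError(f"rates must lie in [0, 1], got H={self.H}, F={self.F}")


def predict(fit, layers, year: int, field_mode: str = "year_specific") -> PredictionSurface:
    """Predict ``lambda_hat = exp(X beta + u) * cell_area`` on the data grid.

    ``field_mode='averaged'`` uses the across-years mean field mode and is
    required for years outside the fitted range.  Standardization constants
    stored at training time are reused verbatim.
    """
    grid = fit.spec.grid
    in_range = grid.years[0] <= year <= grid.years[1]
    if field_mode == "year_specific":
        if not in_range:
            raise ValueError(
                f"year {year} outside fitted range {grid.years}; use field_mode='averaged'")
        u = fit.field_mode[year].values
    elif field_mode == "averaged":
        u = fit.mean_field().values
    else:
        raise ValueError(f"unknown field_mode '{field_mode}'")
    design_year = year if in_range else grid.years[1]
    design = cov.assemble_design(grid, layers, fit.spec.eco_specs,
                                 year=year if _layers_have_year(layers, fit.spec.eco_specs, year) else design_year)
    std = fit.x_scaler.transform(design)
    eta = np.full(grid.n_cells, fit.coef("intercept_nest"))
    for name in std.columns:
        eta += fit.coef(name) * std[name].to_numpy()
    eta = eta.reshape(grid.ny, grid.nx) + u
    lam = np.exp(np.clip(eta, -700, 40)) * grid.cell_area
    return PredictionSurface(year=year, lam=Raster(grid, lam), field_mode=field_mode)


def _layers_have_year(layers, specs, year: int) -> bool:
    for s in specs:
        if s.dynamic:
            entry = layers.get(s.source)
            if isinstance(entry, dict) and year not in entry:
                return False
    return True


def sedi(rates: ConfusionRates | tuple) -> float:
    """Symmetric extremal dependence index of (hit rate, false-alarm rate).

    ``[ln F - ln H - ln(1-F) + ln(1-H)] / [ln F + ln H + ln(1-F) + ln(1-H)]``
    with H, F clamped to [eps, 1-eps]; 0 when H = F, -> 1 for perfect skill.
    """
    H, F = (rates.H, rates.F) if isinstance(rates, ConfusionRates) else rates
    H = min(max(H, _EPS), 1.0 - _EPS)
    F = min(max(F, _EPS), 1.0 - _EPS)
    num = np.log(F) - np.log(H) - np.log1p(-F) + np.log1p(-H)
    den = np.log(F) + np.log(H) + np.log1p(-F) + np.log1p(-H)
    return float(num / den)


def select_threshold(presence_scores, background_scores):
    """Threshold maximizing SEDI over midpoints of sorted unique scores.

    Returns ``(tau, sensitivity, specificity)``; ties prefer the larger
    (more conservative) threshold.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if len(pres) < 1 or len(bg) < 1:
        raise ValueError("need at least one presence and one background score")
    allscores = np.unique(np.concatenate([pres, bg]))
    if len(allscores) < 2:
        raise ValueError("all scores identical: no discrimination possible")
    cands = 0.5 * (allscores[:-1] + allscores[1:])
    best_tau, best_s = None, -np.inf
    for tau in cands:
        H = float(np.mean(pres > tau))
        F = float(np.mean(bg > tau))
        s = sedi((H, F))
        if s > best_s or (s == best_s and (best_tau is None or tau > best_tau)):
            best_s, best_tau = s, tau
    H = float(np.mean(pres > best_tau))
    F = float(np.mean(bg > best_tau))
    return float(best_tau), H, 1.0 - F


def abundance(surface: PredictionSurface, tau: float) -> float:
    """Sum of predicted cell intensities strictly above the threshold."""
    v = surface.lam.values
    return float(np.nansum(np.where(v > tau, v, 0.0)))


def abundance_ci(data, fit_fn, predict_fn, years, tau: float,
                 n_boot: int = 10000, seed: int = 0,
                 resampler=None, max_failure_frac: float = 0.05):
    """Percentile bootstrap interval for the per-year abundance index.

    Presence points are resampled with replacement within stream and year
    (``resampler`` may override, e.g. the identity for tests); ``fit_fn``
    maps a resampled :class:`~ippm.io_core.PointTable` to a fit (the caller
    should hold hyperparameters fixed for a conditional bootstrap), and
    ``predict_fn(fit, year)`` returns a :class:`PredictionSurface`.
    Returns a DataFrame (year, lower, upper) plus the replicate matrix.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    points = data["points"]
    rng = np.random.default_rng(seed)
    reps = np.full((n_boot, len(years)), np.nan)
    failures = 0
    df = points.df
    groups = [(key, grp.index.to_numpy())
              for key, grp in df.groupby(["stream", "year"], sort=True)]
    for b in range(n_boot):
        if resampler is not None:
            table_b = resampler(points, rng)
        else:
            idx = np.concatenate([
                rng.choice(ix, size=len(ix), replace=True) for _, ix in groups])
            table_b = points.__class__(
                df.loc[idx].reset_index(drop=True), grid=points.grid,
                allow_holdout_years=points.allow_holdout_years)
        try:
            fit_b = fit_fn(table_b, b)
            for k, yr in enumerate(years):
                reps[b, k] = abundance(predict_fn(fit_b, yr), tau)
        except (RuntimeError, ValueError, FloatingPointError) as exc:
            failures += 1
            logger.info("bootstrap replicate %d failed: %s", b, exc)
    if failures > max_failure_frac * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed "
            f"(> {max_failure_frac:.0%})")
    lo = np.nanpercentile(reps, 2.5, axis=0)
    hi = np.nanpercentile(reps, 97.5, axis=0)
    table = pd.DataFrame({"year": list(years), "lower": lo, "upper": hi})
    return table, reps


def aggregate_normalize(surface, factor: int) -> Raster:
    """Block-mean aggregation by ``factor`` cells followed by min-max
    rescaling to [0, 1]; a constant surface yields zeros with a warning."""
    ras = surface.lam if isinstance(surface, PredictionSurface) else surface
    g = ras.grid
    nyb = int(np.ceil(g.ny / factor))
    nxb = int(np.ceil(g.nx / factor))
    out = np.full((nyb, nxb), np.nan)
    for jb in range(nyb):
        for ib in range(nxb):
            block = ras.values[jb * factor:(jb + 1) * factor,
                               ib * factor:(ib + 1) * factor]
            if np.any(~np.isnan(block)):
                out[jb, ib] = np.nanmean(block)
    from .io_core import GridSpec

    agg_grid = GridSpec(x0=g.x0, y0=g.y0, dx=g.dx * factor, dy=g.dy * factor,
                        nx=nxb, ny=nyb, years=g.years)
    lo, hi = np.nanmin(out), np.nanmax(out)
    if hi - lo <= 0:
        warnings.warn("constant surface: min-max normalization undefined; "
                      "returning zeros", stacklevel=2)
        return Raster(agg_grid, np.where(np.isnan(out), np.nan, 0.0))
    return Raster(agg_grid, (out - lo) / (hi - lo))
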