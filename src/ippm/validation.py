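"""Transferability assessment: temporal / spatial block and random
cross-validation, variogram-informed block sizing, buffered out-of-sample
evaluation, and the with/without-opportunistic-stream comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .io_core import GridSpec, PointTable, Raster

logger = logging.getLogger("ippm")

__all__ = [
    "FoldAssignment",
    "temporal_folds",
    "spatial_folds",
    "suggest_block_size",
    "auc",
    "cv_run",
    "buffered_eval",
    "stream_ablation",
]


@dataclass
class FoldAssignment:
    """Per-point fold labels plus the scheme that produced them."""

    labels: np.ndarray  # int fold per point
    scheme: str
    n_folds: int
    block_of_point: np.ndarray | None = None  # spatial schemes only
    block_fold: dict | None = None  # block id -> fold
    block_size: float | None = None
    periods: list | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        counts = np.bincount(self.labels, minlength=self.n_folds)
        if (counts == 0).any():
            raise ValueError(
                f"fold(s) {list(np.flatnonzero(counts == 0))} are empty")

    def __len__(self) -> int:
        return len(self.labels)


def temporal_folds(points: PointTable, periods) -> FoldAssignment:
    """Assign each point the index of the (start, end) period containing
    its year."""
    periods = [tuple(p) for p in periods]
    years = points.df["year"].to_numpy()
    labels = np.full(len(years), -1)
    for k, (a, b) in enumerate(periods):
        labels[(years >= a) & (years <= b)] = k
    if (labels < 0).any():
        bad = sorted(set(years[labels < 0]))
        raise ValueError(f"year(s) {bad} outside all periods {periods}")
    return FoldAssignment(labels=labels, scheme="temporal", n_folds=len(periods),
                          periods=periods)


def spatial_folds(points: PointTable, extent: GridSpec, block_size: float,
                  k: int, seed: int = 0) -> FoldAssignment:
    """Tile the extent with square blocks and allocate blocks to ``k``
    folds, greedily balancing presence counts in a seeded block order.
    Points inherit their block's fold."""
    if not block_size > 0:
        raise ValueError("block_size must be positive")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    x, y = points.xy
    bi = np.floor((x - extent.x0) / block_size).astype(int)
    bj = np.floor((extent.y0 - y) / block_size).astype(int)
    nbx = int(np.ceil((extent.x1 - extent.x0) / block_size))
    block_id = bj * nbx + bi
    uniq, counts = np.unique(block_id, return_counts=True)
    if len(uniq) < k:
        raise ValueError(
            f"only {len(uniq)} non-empty blocks for k = {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    # greedy balance: next block goes to the currently lightest fold
    fold_tot = np.zeros(k)
    block_fold: dict[int, int] = {}
    for idx in order:
        f = int(np.argmin(fold_tot))
        block_fold[int(uniq[idx])] = f
        fold_tot[f] += counts[idx]
    labels = np.array([block_fold[int(b)] for b in block_id])
    return FoldAssignment(labels=labels, scheme="spatial_blocks", n_folds=k,
                          block_of_point=block_id, block_fold=block_fold,
                          block_size=block_size)


def _semivariogram(values: np.ndarray, X: np.ndarray, Y: np.ndarray,
                   n_bins: int = 15, max_pairs: int = 5000,
                   rng=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = rng or np.random.default_rng(0)
    ok = ~np.isnan(values)
    v = values[ok]
    xs, ys = X[ok], Y[ok]
    if len(v) > max_pairs:
        pick = rng.choice(len(v), max_pairs, replace=False)
        v, xs, ys = v[pick], xs[pick], ys[pick]
    d = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
    g = 0.5 * (v[:, None] - v[None, :]) ** 2
    iu = np.triu_indices(len(v), 1)
    d, g = d[iu], g[iu]
    dmax = d.max() / 2.0
    edges = np.linspace(0, dmax, n_bins + 1)
    mids, gamma, n = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (d > a) & (d <= b)
        if m.sum() >= 10:
            mids.append(0.5 * (a + b))
            gamma.append(g[m].mean())
            n.append(m.sum())
    return np.array(mids), np.array(gamma), np.array(n)


def suggest_block_size(layers, subsample: int = 2000, seed: int = 0) -> float:
    """Median effective range (3x the exponential range parameter) of
    weighted-least-squares exponential variogram fits to the continuous
    layers; constant or non-convergent layers are skipped."""
    ranges = []
    rng = np.random.default_rng(seed)
    items = layers.values() if isinstance(layers, dict) else layers
    for entry in items:
        rasters = entry.values() if isinstance(entry, dict) else [entry]
        for ras in list(rasters)[:1]:
            if not isinstance(ras, Raster):
                continue
            vals = ras.values
            if np.nanstd(vals) <= 0 or len(np.unique(vals[~np.isnan(vals)])) < 5:
                continue
            X, Y = ras.grid.cell_centers()
            h, gamma, n = _semivariogram(
                vals.ravel(), X.ravel(), Y.ravel(),
                max_pairs=min(subsample, 5000), rng=rng)
            if len(h) < 4:
                continue
            sill0 = float(np.nanvar(vals))

            def model(x, c0, c1, a):
                return c0 + c1 * (1.0 - np.exp(-x / a))

            try:
                popt, _ = curve_fit(
                    model, h, gamma,
                    p0=[0.0, sill0, max(h.max() / 3.0, ras.grid.dx)],
                    sigma=1.0 / np.sqrt(n), absolute_sigma=False,
                    bounds=([0, 1e-12, ras.grid.dx * 0.05],
                            [np.inf, np.inf, h.max() * 10]),
                    maxfev=5000)
            except (RuntimeError, ValueError):
                logger.info("variogram fit failed for a layer; skipping")
                continue
            c0, c1, a = popt
            if c1 < 0.1 * (c0 + c1):
                # nugget-dominated (white noise): no spatial structure
                ranges.append(float(ras.grid.dx))
            else:
                ranges.append(min(3.0 * a, float(h.max())))
    if not ranges:
        raise RuntimeError("no layer produced a convergent variogram fit")
    return float(np.median(ranges))


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 P(tie)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    rp = ranks[: len(p)].sum()
    u = rp - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


def _score_fold(fit_res, layers, held_points: PointTable, held_bg,
                predict_years) -> tuple[float, float, int]:
    """AUC and RMSE for one held-out set.

    ``held_bg`` is a dict with arrays x, y, year, w for held-out quadrature
    points.  Presence scores are lambda-hat per unit area at the point's
    cell; RMSE uses the presence score p = 1 - exp(-lambda * w).
    """
    from .predict_assess import predict

    surfaces = {}
    for yr in predict_years:
        in_range = fit_res.spec.grid.years[0] <= yr <= fit_res.spec.grid.years[1]
        surfaces[yr] = predict(
            fit_res, layers, yr,
            field_mode="year_specific" if in_range else "averaged")

    def lam_at(x, y, year):
        out = np.empty(len(x))
        for yr in np.unique(year):
            m = year == yr
            s = surfaces[int(yr)]
            g = s.lam.grid
            i, j = g.cell_of(x[m], y[m])
            i = np.clip(i, 0, g.nx - 1)
            j = np.clip(j, 0, g.ny - 1)
            out[m] = s.lam.values[j, i] / g.cell_area
        return out

    px, py = held_points.xy
    pyear = held_points.df["year"].to_numpy()
    lam_p = lam_at(px, py, pyear)
    lam_b = lam_at(held_bg["x"], held_bg["y"], held_bg["year"])
    a = auc(lam_p, lam_b)
    z = np.concatenate([np.ones(len(lam_p)), np.zeros(len(lam_b))])
    w = np.concatenate([np.full(len(lam_p), held_bg["w"].mean()), held_bg["w"]])
    p_hat = 1.0 - np.exp(-np.concatenate([lam_p, lam_b]) * w)
    rmse = float(np.sqrt(np.mean((z - p_hat) ** 2)))
    return a, rmse, len(lam_p)


def cv_run(assignment: FoldAssignment, model_config: dict, data: dict,
           seed: int = 0, streams=("nest", "ebird")) -> pd.DataFrame:
    """Fit-on-train / score-on-test for every fold.

    ``model_config`` supplies the :class:`~ippm.integrated_fit.ModelSpec`
    keyword arguments (and optional ``fit_kwargs``).  Held-out background
    points are fresh uniform quadrature points restricted to the held-out
    blocks / periods.  Returns per-fold rows plus a pooled row
    (point-weighted mean over folds).
    """
    from . import integrated_fit as ifit
    from .ppm_lasso import build_quadrature

    points: PointTable = data["points"]
    layers = data["layers"]
    grid: GridSpec = model_config["grid"]
    fit_kwargs = dict(model_config.get("fit_kwargs", {}))
    spec_kwargs = {k: v for k, v in model_config.items()
                   if k not in ("fit_kwargs",)}
    rows = []
    for f in range(assignment.n_folds):
        te = assignment.labels == f
        tr = ~te
        train = points.subset(tr)
        test = points.subset(te)
        if len(test) == 0 or len(train.stream("nest")) == 0:
            logger.info("cv_run: skipping degenerate fold %d", f)
            continue
        spec = ifit.ModelSpec(**spec_kwargs)
        try:
            res = ifit.fit(spec, {"points": train, "layers": layers},
                           seed=seed + f, streams=streams, **fit_kwargs)
        except (RuntimeError, ValueError) as exc:
            logger.info("cv_run: fold %d fit failed (%s); skipped", f, exc)
            continue
        bg = build_quadrature(grid, max(1000, 200 * assignment.n_folds),
                              seed=seed + 90000 + f)
        bmask = _held_mask(assignment, f, bg, grid)
        if bmask.sum() < 10:
            logger.info("cv_run: fold %d has too little held-out background", f)
            continue
        held_bg = {"x": bg.x[bmask], "y": bg.y[bmask],
                   "year": bg.year[bmask], "w": bg.w[bmask]}
        years = sorted(set(test.df["year"]))
        a, rmse, n_p = _score_fold(res, layers, test, held_bg, years)
        rows.append({"fold": f, "auc": a, "rmse": rmse, "n_presence": n_p})
    if not rows:
        raise RuntimeError("all folds degenerate: no CV metrics computed")
    table = pd.DataFrame(rows)
    wts = table["n_presence"].to_numpy(dtype=float)
    pooled = {
        "fold": -1,
        "auc": float(np.average(table["auc"], weights=wts)),
        "rmse": float(np.average(table["rmse"], weights=wts)),
        "n_presence": int(wts.sum()),
    }
    return pd.concat([table, pd.DataFrame([pooled])], ignore_index=True)


def _held_mask(assignment: FoldAssignment, f: int, bg, grid: GridSpec):
    if assignment.scheme == "temporal":
        lab = np.full(len(bg.x), -1)
        for k, (a, b) in enumerate(assignment.periods):
            lab[(bg.year >= a) & (bg.year <= b)] = k
        return lab == f
    if assignment.scheme == "spatial_blocks":
        bs = assignment.block_size
        nbx = int(np.ceil((grid.x1 - grid.x0) / bs))
        bi = np.floor((bg.x - grid.x0) / bs).astype(int)
        bj = np.floor((grid.y0 - bg.y) / bs).astype(int)
        bid = bj * nbx + bi
        return np.array([assignment.block_fold.get(int(b), -1) == f for b in bid])
    # random scheme: hold out a seeded share of background everywhere
    rng = np.random.default_rng(f)
    return rng.random(len(bg.x)) < 1.0 / assignment.n_folds


def random_folds(points: PointTable, k: int, seed: int = 0) -> FoldAssignment:
    rng = np.random.default_rng(seed)
    lab = np.tile(np.arange(k), len(points) // k + 1)[: len(points)]
    rng.shuffle(lab)
    return FoldAssignment(labels=lab, scheme="random", n_folds=k)


def buffered_eval(checklists: PointTable, surface, labels) -> tuple[float, float]:
    """Score each checklist by the maximum predicted cell value whose
    center falls within the checklist's effort-distance buffer, then
    compute (AUC, RMSE) against the presence labels.

    ``effort_distance`` is km; radius 0 scores the containing cell.
    Buffers holding no cell centers drop the checklist with a log entry.
    """
    from .predict_assess import PredictionSurface

    ras = surface.lam if isinstance(surface, PredictionSurface) else surface
    g = ras.grid
    X, Y = g.cell_centers()
    labels = np.asarray(labels, dtype=float)
    scores, kept = [], []
    df = checklists.df
    for idx, row in df.iterrows():
        r = (row["effort_distance"] or 0.0) * 1000.0
        if np.isnan(r):
            r = 0.0
        if r <= 0:
            i, j = g.cell_of(row["x"], row["y"])
            i = int(np.clip(i, 0, g.nx - 1))
            j = int(np.clip(j, 0, g.ny - 1))
            val = ras.values[j, i]
        else:
            m = (X - row["x"]) ** 2 + (Y - row["y"]) ** 2 <= r**2
            if not m.any():
                logger.info("buffered_eval: checklist %d buffer holds no cell "
                            "centers; dropped", idx)
                continue
            with np.errstate(all="ignore"):
                val = np.nanmax(ras.values[m])
        if np.isnan(val):
            logger.info("buffered_eval: checklist %d sees only missing cells", idx)
            continue
        scores.append(val)
        kept.append(idx)
    scores = np.asarray(scores)
    lab = labels[np.asarray(kept, dtype=int)]
    if (lab == 1).any() and (lab == 0).any():
        a = auc(scores[lab == 1], scores[lab == 0])
    else:
        a = float("nan")  # single-class labels: discrimination undefined
    p_hat = 1.0 - np.exp(-scores)
    rmse = float(np.sqrt(np.mean((lab - p_hat) ** 2)))
    return a, rmse


def stream_ablation(data: dict, model_config: dict, seed: int = 0,
                    folds: int = 10) -> pd.DataFrame:
    """Random K-fold comparison of the integrated model against the
    nests-only model on identical folds."""
    points: PointTable = data["points"]
    if len(points.stream("nest")) == 0:
        raise ValueError("nest stream required")
    assignment = random_folds(points, folds, seed=seed)
    full = cv_run(assignment, model_config, data, seed=seed,
                  streams=("nest", "ebird"))
    nest_cfg = dict(model_config)
    nest_cfg["obs_specs"] = []
    nests = cv_run(assignment, nest_cfg, data, seed=seed, streams=("nest",))
    full_p = full[full["fold"] == -1].iloc[0]
    nest_p = nests[nests["fold"] == -1].iloc[0]
    return pd.DataFrame([
        {"model": "integrated", "auc": full_p["auc"], "rmse": full_p["rmse"]},
        {"model": "nests_only", "auc": nest_p["auc"], "rmse": nest_p["rmse"]},
    ])
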