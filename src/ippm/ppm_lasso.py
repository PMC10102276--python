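"""Quadrature-approximated Poisson point process regression with LASSO.

The point process log-likelihood is approximated on a scheme of presence
plus background points with areal weights (a Berman-Turner construction).
With response ``y_i = z_i / w_i`` and weights ``w_i`` the weighted Poisson
deviance matches the point process likelihood, so penalized fitting reduces
to a weighted Poisson GLM with an L1 penalty, solved here by iteratively
reweighted least squares with cyclic coordinate descent and soft
thresholding (the glmnet recipe, but with the penalty on the raw weighted
likelihood rather than the per-observation mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GridSpec, PointTable

logger = logging.getLogger("ippm")

__all__ = [
    "QuadratureScheme",
    "PenalizedFit",
    "build_quadrature",
    "dwpr_fit",
    "lambda_max",
    "select_scale",
    "lasso_cv",
    "compare_models",
    "presence_score",
]

_ETA_CAP = 40.0  # guard against exp overflow inside IRLS


@dataclass
class QuadratureScheme:
    """Presence + background points with areal weights.

    ``z`` is 1 on presence rows, 0 on background rows; weights are m^2 per
    point-year and sum to the study area |A| within each year stratum.
    """

    x: np.ndarray
    y: np.ndarray
    year: np.ndarray
    w: np.ndarray
    z: np.ndarray
    area: float

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "year", "w", "z"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"scheme field '{name}' length mismatch")
        if np.any(self.w <= 0):
            raise ValueError("all quadrature weights must be positive")
        for yr in np.unique(self.year):
            s = self.w[self.year == yr].sum()
            if abs(s - self.area) > 1e-6 * self.area:
                raise ValueError(
                    f"weights for year {yr} sum to {s}, expected |A| = {self.area}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_presence(self) -> int:
        return int(self.z.sum())

    def subset(self, mask: np.ndarray) -> "QuadratureScheme":
        """Row subset *without* re-normalizing weights (for CV folds)."""
        out = QuadratureScheme.__new__(QuadratureScheme)
        out.x = self.x[mask]
        out.y = self.y[mask]
        out.year = self.year[mask]
        out.w = self.w[mask]
        out.z = self.z[mask]
        out.area = self.area
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "year": self.year, "w": self.w, "z": self.z})


@dataclass
class PenalizedFit:
    """Result of one penalized DWPR fit."""

    intercept: float
    coef: np.ndarray
    columns: list[str]
    penalty: float
    n_iter: int = 0
    converged: bool = True
    cv_rmse: float | None = None
    cv_auc: float | None = None
    fold_rmse: list[float] = field(default_factory=list)
    path: pd.DataFrame | None = None

    @property
    def nonzero(self) -> list[str]:
        return [c for c, b in zip(self.columns, self.coef) if b != 0.0]

    def linpred(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


def build_quadrature(region, m: int, years=None, seed=0,
                     presences: PointTable | None = None,
                     presence_weight: str = "uniform",
                     method: str = "uniform") -> QuadratureScheme:
    """Uniform background points plus presence points, with areal weights
    per year stratum.

    ``region`` is a :class:`GridSpec` (the rectangular extent is used).  The
    ``m`` background points are allocated evenly across years.  With
    ``presence_weight='uniform'`` every point (background and presence) in
    year t receives weight ``|A| / (n_background_t + n_presence_t)``; with
    ``'epsilon'`` presence nodes get a negligible weight (1e-8) and
    background nodes ``|A| / n_background_t``, which removes the
    integral-estimate bias where presences cluster (the downweighted
    construction of the DWPR literature).  Both variants conserve the
    per-year weight sum to |A| within 1e-6 relative.
    """
    if presence_weight not in ("uniform", "epsilon"):
        raise ValueError(f"unknown presence_weight '{presence_weight}'")
    if method not in ("uniform", "stratified"):
        raise ValueError(f"unknown method '{method}'")
    if m < 100:
        raise ValueError(f"need at least 100 background points, got {m}")
    grid: GridSpec = region
    area = grid.area
    if not area > 0:
        raise ValueError("degenerate region: zero area")
    if years is None:
        years = grid.year_list
    years = list(years)
    rng = np.random.default_rng(seed)
    per_year = np.full(len(years), m // len(years))
    per_year[: m % len(years)] += 1
    xs, ys, yrs, zs = [], [], [], []
    for yr, k in zip(years, per_year):
        if method == "stratified":
            # jittered allocation over cells: near-equal points per cell,
            # which shrinks the integral-estimate variance from O(1/m)
            cells = np.tile(np.arange(grid.n_cells), k // grid.n_cells + 1)[:k]
            rng.shuffle(cells)
            ci = cells % grid.nx
            cj = cells // grid.nx
            xs.append(grid.x0 + (ci + rng.random(k)) * grid.dx)
            ys.append(grid.y0 - (cj + rng.random(k)) * grid.dy)
        else:
            xs.append(grid.x0 + rng.random(k) * (grid.x1 - grid.x0))
            ys.append(grid.y1 + rng.random(k) * (grid.y0 - grid.y1))
        yrs.append(np.full(k, yr))
        zs.append(np.zeros(k))
    if presences is not None and len(presences):
        px, py = presences.xy
        xs.append(px)
        ys.append(py)
        yrs.append(presences.df["year"].to_numpy())
        zs.append(np.ones(len(presences)))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    year = np.concatenate(yrs).astype(int)
    z = np.concatenate(zs)
    w = np.empty(len(x))
    for yr in np.unique(year):
        mask = year == yr
        if presence_weight == "uniform":
            w[mask] = area / mask.sum()
        else:
            bg = mask & (z == 0)
            w[bg] = area / bg.sum()
            w[mask & (z == 1)] = 1e-8
    return QuadratureScheme(x=x, y=y, year=year, w=w, z=z, area=area)


def _soft(v: float, t: float) -> float:
    if v > t:
        return v - t
    if v < -t:
        return v + t
    return 0.0


def dwpr_fit(design, scheme: QuadratureScheme, penalty: float = 0.0,
             tol: float = 1e-8, max_iter: int = 200,
             init: PenalizedFit | None = None) -> PenalizedFit:
    """Maximize the weighted Poisson point process likelihood with an L1
    penalty on the slopes (intercept unpenalized).

    The objective is ``sum_i w_i (y_i eta_i - exp(eta_i)) - penalty *
    sum_j |beta_j|`` with ``y_i = z_i / w_i``; convergence is declared when
    the largest coefficient change in a full IRLS/coordinate-descent cycle
    falls below ``tol``.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    columns = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != len(scheme):
        raise ValueError("design rows do not align with quadrature scheme")
    if np.isnan(X).any():
        raise ValueError("design contains missing values")
    w = scheme.w
    z = scheme.z  # counts: w*y
    n, p = X.shape
    if init is not None and len(init.coef) == p:
        beta = init.coef.copy()
        alpha = init.intercept
        eta = alpha + X @ beta
    else:
        beta = np.zeros(p)
        alpha = np.log(max(z.sum(), 0.5) / w.sum())  # homogeneous start
        eta = np.full(n, alpha)

    def objective(e, b):
        return float((w * np.exp(np.clip(e, -_ETA_CAP, _ETA_CAP))).sum()
                     - e @ z + penalty * np.abs(b).sum())

    f_prev = objective(eta, beta)
    for it in range(max_iter):
        v = w * np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))  # IRLS weights
        # working response of the quadratic approximation at (alpha, beta)
        r = z - v  # score residual on the count scale
        a0 = float(v.sum())
        aj = v @ X**2
        alpha_new, beta_new, eta_q = alpha, beta.copy(), eta.copy()
        # cyclic coordinate descent to convergence on the fixed quadratic
        for _ in range(100):
            inner_max = 0.0
            # intercept: quadratic-model gradient (v.(eta_q - eta) - r) . 1
            g0 = float((v * (eta_q - eta) - r).sum())
            d0 = -g0 / a0
            alpha_new += d0
            eta_q += d0
            inner_max = max(inner_max, abs(d0))
            for j in range(p):
                if aj[j] <= 0:
                    continue
                xj = X[:, j]
                gj = float((v * (eta_q - eta) - r) @ xj)
                u = aj[j] * beta_new[j] - gj
                new = _soft(u, penalty) / aj[j]
                d = new - beta_new[j]
                if d != 0.0:
                    beta_new[j] = new
                    eta_q += d * xj
                    inner_max = max(inner_max, abs(d))
            if inner_max < max(tol, 1e-11):
                break
        # damped update: halve the step while the true objective increases
        t = 1.0
        for _ in range(40):
            e_try = eta + t * (eta_q - eta)
            b_try = beta + t * (beta_new - beta)
            f_try = objective(e_try, b_try)
            if f_try <= f_prev + 1e-12 * max(1.0, abs(f_prev)):
                break
            t *= 0.5
        delta_max = float(max(abs(t * (alpha_new - alpha)),
                              np.max(np.abs(t * (beta_new - beta))) if p else 0.0))
        alpha += t * (alpha_new - alpha)
        beta += t * (beta_new - beta)
        eta = eta + t * (eta_q - eta)
        stagnated = abs(f_prev - f_try) <= 1e-13 * max(1.0, abs(f_prev))
        f_prev = f_try
        if delta_max < tol or stagnated:
            return PenalizedFit(intercept=alpha, coef=beta, columns=columns,
                                penalty=penalty, n_iter=it + 1, converged=True)
    raise RuntimeError(
        f"dwpr_fit did not converge in {max_iter} iterations "
        f"(last max coefficient change {delta_max:.3e}, penalty={penalty})")


def lambda_max(design, scheme: QuadratureScheme) -> float:
    """Smallest penalty at which every slope is zero."""
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    w, z = scheme.w, scheme.z
    alpha = np.log(z.sum() / w.sum())
    mu = w * np.exp(alpha)
    return float(np.max(np.abs((z - mu) @ X)))


def presence_score(fit_or_eta, scheme: QuadratureScheme, design=None) -> np.ndarray:
    """Per-row presence score p_hat = 1 - exp(-lambda_hat * w): the
    probability a Poisson cell with mean lambda*w holds at least one point."""
    if isinstance(fit_or_eta, PenalizedFit):
        X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design)
        eta = fit_or_eta.linpred(X)
    else:
        eta = np.asarray(fit_or_eta, dtype=float)
    lam = np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))
    return 1.0 - np.exp(-lam * scheme.w)


def _fold_labels(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    lab = np.tile(np.arange(folds), n // folds + 1)[:n]
    rng.shuffle(lab)
    return lab


def _make_folds(scheme: QuadratureScheme, folds: int, seed: int) -> np.ndarray:
    """Row-level fold labels; refolds (with logging) until every fold's
    training complement holds at least one presence and one background
    point (so every fold is fittable; leave-one-out remains legal)."""
    n_pres = scheme.z.sum()
    n_bg = (scheme.z == 0).sum()
    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        lab = _fold_labels(len(scheme), folds, rng)
        ok = all(
            n_pres - scheme.z[lab == f].sum() > 0
            and n_bg - (scheme.z[lab == f] == 0).sum() > 0
            for f in range(folds)
        )
        if ok:
            if attempt:
                logger.info("refolded %d times to avoid presence-free training sets",
                            attempt)
            return lab
    raise RuntimeError("could not build folds with presences in every training set")


def _cv_metrics(z, p_hat, eta):
    resid = z - p_hat
    rmse = float(np.sqrt(np.mean(resid**2)))
    from .validation import auc as _auc

    a = _auc(eta[z == 1], eta[z == 0]) if (z == 1).any() and (z == 0).any() else np.nan
    return rmse, a


def select_scale(covariate: str, candidate_scales, scheme: QuadratureScheme,
                 layers, folds: int = 10, seed: int = 0, stat: str = "mean",
                 dynamic: bool = False) -> tuple[str, pd.DataFrame]:
    """Pick the covariate's spatial scale by 10-fold CV RMSE of univariate
    unpenalized DWPR fits; ties break toward the smaller scale."""
    from .covariates import CovariateSpec, assemble_design

    candidate_scales = list(candidate_scales)
    order = {s: i for i, s in enumerate(
        ("pixel30", "neighbor", "r90", "r150", "r300", "r750"))}
    candidate_scales.sort(key=lambda s: order[s])
    lab = _make_folds(scheme, folds, seed)
    frame = scheme.to_frame()
    rows = []
    cache: dict = {}
    for scale in candidate_scales:
        spec = CovariateSpec(name=covariate, source=covariate, scale=scale,
                             stat=stat, dynamic=dynamic)
        design = assemble_design(frame, layers, [spec], cache=cache)
        col = design.to_numpy()
        sd = col.std(ddof=1)
        if sd > 0:
            col = (col - col.mean()) / sd
        errs = []
        for f in range(folds):
            tr, te = lab != f, lab == f
            try:
                fit = dwpr_fit(col[tr], scheme.subset(tr), penalty=0.0)
            except RuntimeError:
                errs = None
                break
            eta = fit.linpred(col[te])
            p_hat = presence_score(eta, scheme.subset(te))
            errs.append(np.sqrt(np.mean((scheme.z[te] - p_hat) ** 2)))
        if errs is None:
            continue
        rows.append({"scale": scale, "rmse": float(np.mean(errs))})
    if not rows:
        raise RuntimeError(f"all scale fits failed for '{covariate}'")
    table = pd.DataFrame(rows)
    best = table.loc[table["rmse"].idxmin(), "scale"]  # idxmin: first minimum
    return str(best), table


def lasso_cv(design, scheme: QuadratureScheme, folds: int = 10, seed: int = 0,
             n_penalties: int = 50, decades: float = 2.0) -> PenalizedFit:
    """LASSO path with K-fold cross-validation.

    The penalty grid runs from ``lambda_max`` down ``decades`` decades in
    ``n_penalties`` log-spaced values.  The selected penalty minimizes the
    mean CV RMSE, with ties broken toward the larger penalty (the sparser
    model); since fold RMSE is a Monte Carlo estimate, penalties whose mean
    RMSE lies within one standard error of the minimum count as tied (the
    cv.glmnet one-SE convention).  The returned fit is refit on all rows at
    that penalty, with AUC reported there.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    lmax = lambda_max(design, scheme)
    grid = np.geomspace(lmax, lmax / 10**decades, n_penalties)
    lab = _make_folds(scheme, folds, seed)
    fold_rmse = np.zeros((folds, n_penalties))
    for f in range(folds):
        tr, te = lab != f, lab == f
        sub_tr, sub_te = scheme.subset(tr), scheme.subset(te)
        warm = None
        for k, pen in enumerate(grid):
            fit = dwpr_fit(X[tr], sub_tr, penalty=pen, init=warm)
            warm = fit
            eta = fit.linpred(X[te])
            p_hat = presence_score(eta, sub_te)
            fold_rmse[f, k] = np.sqrt(np.mean((sub_te.z - p_hat) ** 2))
    mean_rmse = fold_rmse.mean(axis=0)
    k_min = int(np.argmin(mean_rmse))
    se_min = float(fold_rmse[:, k_min].std(ddof=1) / np.sqrt(folds))
    # ties toward larger penalty: grid is descending, first index within one
    # SE of the minimum is the sparsest model statistically tied with it
    best_k = int(np.argmax(mean_rmse <= mean_rmse[k_min] + se_min))
    best_pen = float(grid[best_k])
    final = dwpr_fit(X, scheme, penalty=best_pen)
    eta = final.linpred(X)
    p_hat = presence_score(eta, scheme)
    rmse, a = _cv_metrics(scheme.z, p_hat, eta)
    final.cv_rmse = float(mean_rmse[best_k])
    final.cv_auc = a
    final.fold_rmse = list(fold_rmse[:, best_k])
    cols = list(design.columns) if isinstance(design, pd.DataFrame) else final.columns
    path_rows = []
    for k, pen in enumerate(grid):
        path_rows.append({"penalty": float(pen), "cv_rmse": float(mean_rmse[k])})
    final.path = pd.DataFrame(path_rows)
    final.columns = cols
    return final


def compare_models(candidates: dict, scheme: QuadratureScheme, folds: int = 10,
                   seed: int = 0, n_penalties: int = 30) -> pd.DataFrame:
    """Cross-validate several candidate designs on identical folds.

    ``candidates`` maps model name -> design DataFrame (rows aligned with
    the scheme).  Each candidate is scored at its own CV-optimal LASSO
    penalty; the table is ranked by RMSE (then AUC).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    lab = _make_folds(scheme, folds, seed)
    rows = []
    for name, design in candidates.items():
        X = design.to_numpy(dtype=float)
        lmax = lambda_max(design, scheme)
        grid = np.geomspace(lmax, lmax / 100.0, n_penalties)
        fold_rmse = np.zeros((folds, n_penalties))
        fold_auc = np.zeros(folds)
        for f in range(folds):
            tr, te = lab != f, lab == f
            sub_tr, sub_te = scheme.subset(tr), scheme.subset(te)
            warm = None
            for k, pen in enumerate(grid):
                fit = dwpr_fit(X[tr], sub_tr, penalty=pen, init=warm)
                warm = fit
                eta = fit.linpred(X[te])
                p_hat = presence_score(eta, sub_te)
                fold_rmse[f, k] = np.sqrt(np.mean((sub_te.z - p_hat) ** 2))
        mean_rmse = fold_rmse.mean(axis=0)
        best_k = int(np.argmin(np.round(mean_rmse, 12)))
        # AUC at the selected penalty, per fold
        from .validation import auc as _auc

        for f in range(folds):
            tr, te = lab != f, lab == f
            fit = dwpr_fit(X[tr], scheme.subset(tr), penalty=grid[best_k])
            eta = fit.linpred(X[te])
            zt = scheme.z[te]
            fold_auc[f] = _auc(eta[zt == 1], eta[zt == 0])
        rows.append({
            "model": name,
            "rmse": float(mean_rmse[best_k]),
            "auc": float(np.nanmean(fold_auc)),
            "penalty": float(grid[best_k]),
        })
    table = pd.DataFrame(rows).sort_values(
        ["rmse", "auc"], ascending=[True, False], kind="stable").reset_index(drop=True)
    return table
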