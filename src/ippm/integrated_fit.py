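"""Joint latent-intensity model for the two presence streams.

Both streams share a log intensity ``eta(s,t) = b0 + X(s,t) beta + u(s,t)``
with a lattice Matern x AR1 field ``u``; the opportunistic stream is
thinned by ``b(s) = exp(d0 + Z(s) delta)``.  Each stream's point process
likelihood is approximated on its own quadrature scheme.

Inference is MAP with a nested Laplace approximation: for fixed field
hyperparameters the joint posterior over (beta, delta, u) is maximized by
Newton iterations with an exact sparse Hessian; the hyperparameters
(rho, sigma, phi) maximize the Laplace-approximate marginal posterior with
penalized-complexity priors.  Credible intervals come from the Gaussian
approximation at the joint mode (so the reported medians equal the modes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from . import covariates as cov
from . import random_field as rf
from .io_core import GridSpec, PointTable, Raster
from .ppm_lasso import QuadratureScheme, build_quadrature

logger = logging.getLogger("ippm")

__all__ = ["ModelSpec", "FitResult", "joint_loglik", "fit", "fit_without_stream"]

_L_CAP = 40.0


@dataclass
class ModelSpec:
    """Declarative description of one integrated fit."""

    grid: GridSpec
    eco_specs: list
    obs_specs: list = dc_field(default_factory=list)
    prior_prec: float = 0.001
    field_init: rf.FieldParams = dc_field(
        default_factory=lambda: rf.FieldParams(rho=1.0, sigma=1.0, phi=0.5))
    pc_prior: dict = dc_field(default_factory=dict)  # rho0, alpha_rho, sigma0, alpha_sigma
    coarsen: int = 1
    m_quad: int | None = None  # background points per stream
    optimize_hyperparams: bool = True
    max_outer: int = 40
    n_restarts: int = 3
    n_sd_probes: int = 16
    fixed_sigma: float | None = None  # set ~0 to disable the field
    point_sampling: str = "bilinear"  # or "nearest" (cell value at points)

    def __post_init__(self) -> None:
        if self.field_init.rho < 2 * self.grid.dx * self.coarsen:
            self.field_init = rf.FieldParams(
                rho=2.0 * self.grid.dx * self.coarsen + 1e-9,
                sigma=self.field_init.sigma, phi=self.field_init.phi)
        if not self.pc_prior:
            diam = float(np.hypot(self.grid.x1 - self.grid.x0,
                                  self.grid.y0 - self.grid.y1))
            self.pc_prior = {"rho0": diam / 4.0, "alpha_rho": 0.5,
                             "sigma0": 1.0, "alpha_sigma": 0.05}


@dataclass
class FitResult:
    """Posterior summaries, field mode, and diagnostics of one fit."""

    coefficients: pd.DataFrame  # name, block, q2.5, q50, q97.5, sd
    hyperparams: dict
    field_mode: dict  # year -> Raster on the data grid
    field_sd: Raster | None
    marginal_loglik: float
    diagnostics: dict
    spec: ModelSpec
    x_scaler: cov.Standardizer
    z_scaler: cov.Standardizer | None
    coarse_grid: GridSpec
    u_vector: np.ndarray  # coarse-lattice field mode, year-major
    streams: tuple = ("nest", "ebird")

    def coef(self, name: str) -> float:
        row = self.coefficients.set_index("name").loc[name]
        return float(row["q50"])

    def coef_sd(self, name: str) -> float:
        row = self.coefficients.set_index("name").loc[name]
        return float(row["sd"])

    @property
    def beta(self) -> pd.DataFrame:
        return self.coefficients[self.coefficients["block"] == "ecological"]

    @property
    def delta(self) -> pd.DataFrame:
        return self.coefficients[self.coefficients["block"] == "observation"]

    def mean_field(self) -> Raster:
        """Across-years mean of the field mode on the data grid."""
        vals = np.mean([r.values for r in self.field_mode.values()], axis=0)
        some = next(iter(self.field_mode.values()))
        return Raster(some.grid, vals)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _field_at(u, grid: GridSpec, x, y, year) -> np.ndarray:
    """Evaluate a per-year field (dict year -> Raster, or ndarray
    (n_years, ny, nx)) at point locations by cell membership."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    year = np.asarray(year)
    i, j = grid.cell_of(x, y)
    i = np.clip(i, 0, grid.nx - 1)
    j = np.clip(j, 0, grid.ny - 1)
    out = np.empty(len(x))
    if isinstance(u, dict):
        for yr in np.unique(year):
            m = year == yr
            out[m] = u[int(yr)].values[j[m], i[m]]
    else:
        for k, yr in enumerate(grid.year_list):
            m = year == yr
            out[m] = u[k][j[m], i[m]]
    return out


def joint_loglik(beta, delta, u, schemes: dict, designs: dict, grid: GridSpec,
                 intercepts=(0.0, 0.0)) -> float:
    """Quadrature-approximated joint log-likelihood of both streams.

    ``schemes`` maps stream name -> :class:`QuadratureScheme`; ``designs``
    maps stream -> ecological design matrix aligned with scheme rows, plus
    ``'ebird_obs'`` -> observation design for the ebird scheme.  ``u`` is a
    per-year field (dict of rasters or array); pass ``None`` for a zero
    field.  Returns  sum_presence log lambda (+ log b on ebird) minus the
    quadrature integrals of lambda and lambda*b.
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float) if delta is not None else np.zeros(0)
    b0, d0 = intercepts
    total = 0.0
    for name, scheme in schemes.items():
        X = np.asarray(designs[name], dtype=float)
        ell = np.full(len(scheme), b0, dtype=float)
        if beta.size:
            ell += X @ beta
        if u is not None:
            ell += _field_at(u, grid, scheme.x, scheme.y, scheme.year)
        if name == "ebird":
            Z = np.asarray(designs["ebird_obs"], dtype=float)
            ell += d0
            if delta.size:
                ell += Z @ delta
        if not np.all(np.isfinite(ell)):
            bad = int(np.argmax(~np.isfinite(ell)))
            raise FloatingPointError(
                f"non-finite linear predictor at scheme row {bad} "
                f"({scheme.x[bad]:.1f}, {scheme.y[bad]:.1f})")
        pres = scheme.z == 1
        total += float(ell[pres].sum() - (scheme.w * np.exp(ell)).sum())
    return total


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------


def _coarse_grid(grid: GridSpec, factor: int) -> GridSpec:
    nxc = int(np.ceil(grid.nx / factor))
    nyc = int(np.ceil(grid.ny / factor))
    return GridSpec(x0=grid.x0, y0=grid.y0, dx=grid.dx * factor,
                    dy=grid.dy * factor, nx=nxc, ny=nyc, years=grid.years)


class _Problem:
    """Assembled sparse design, counts and weights for the joint fit."""

    def __init__(self, spec: ModelSpec, points: PointTable, layers, seed: int,
                 streams=("nest", "ebird"), x_scaler=None, z_scaler=None,
                 m_quad: int | None = None):
        grid = spec.grid
        self.spec = spec
        self.streams = tuple(s for s in streams
                             if len(points.stream(s)) > 0 or s == "nest")
        self.grid = grid
        self.cgrid = _coarse_grid(grid, spec.coarsen)
        self.n_cells = self.cgrid.n_cells
        self.n_years = grid.n_years
        self.n_u = self.n_cells * self.n_years
        cache: dict = {}

        # quadrature spans only years with training data: a year absent from
        # the table (e.g. a held-out CV period) must not enter the likelihood
        # as a presence-free year
        data_years = sorted(set(points.df["year"])) or grid.year_list

        rows_X, rows_Z, rows_w, rows_z, rows_xy = [], [], [], [], []
        self.schemes = {}
        for k, s in enumerate(self.streams):
            pres = points.stream(s)
            m = m_quad or spec.m_quad or max(5000, 20 * len(pres))
            # epsilon presence weights: at desk-scale quadrature densities the
            # uniform scheme biases the intensity integral upward inside
            # presence clusters, attenuating coefficients
            scheme = build_quadrature(grid, m, years=data_years,
                                      seed=seed + 1000 * k,
                                      presences=pres, presence_weight="epsilon",
                                      method="stratified")
            self.schemes[s] = scheme
            frame = scheme.to_frame()
            bil = spec.point_sampling == "bilinear"
            X = cov.assemble_design(frame, layers, spec.eco_specs, cache=cache,
                                    bilinear=bil)
            rows_X.append(X)
            if s == "ebird" and spec.obs_specs:
                Z = cov.assemble_design(frame, layers, spec.obs_specs, cache=cache,
                                        bilinear=bil)
            else:
                Z = None
            rows_Z.append(Z)
            rows_w.append(scheme.w)
            rows_z.append(scheme.z)
            rows_xy.append(frame)

        X_all = pd.concat(rows_X, ignore_index=True)
        keep = ~X_all.isna().any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("integrated fit: dropping %d rows with missing covariates",
                        dropped)
        self.x_scaler = x_scaler or cov.Standardizer.fit(X_all[keep])
        X_std = self.x_scaler.transform(X_all).to_numpy(dtype=float)

        self.has_obs = any(Z is not None for Z in rows_Z)
        if self.has_obs:
            Z_cat = pd.concat([Z for Z in rows_Z if Z is not None],
                              ignore_index=True)
            self.z_scaler = z_scaler or cov.Standardizer.fit(Z_cat.dropna())
            self.z_cols = list(Z_cat.columns)
        else:
            self.z_scaler = None
            self.z_cols = []

        n_rows = len(X_all)
        p_x = X_std.shape[1]
        p_z = len(self.z_cols)
        self.x_cols = list(X_all.columns)
        self.n_beta = 1 + p_x  # intercept + slopes
        self.n_delta = (1 + p_z) if self.has_obs else 0

        # block design: [1 | X | (1 | Z) on ebird rows | A]
        blocks = [np.ones((n_rows, 1)), X_std]
        zmat = np.zeros((n_rows, self.n_delta))
        offset = 0
        for s, Z, frame in zip(self.streams, rows_Z, rows_xy):
            n_s = len(frame)
            if Z is not None:
                Zs = self.z_scaler.transform(Z).to_numpy(dtype=float)
                zmat[offset:offset + n_s, 0] = 1.0
                zmat[offset:offset + n_s, 1:] = Zs
            offset += n_s
        if self.n_delta:
            blocks.append(zmat)
        dense = np.hstack(blocks)
        keep_np = keep.to_numpy()
        if self.n_delta:
            keep_np &= ~np.isnan(zmat).any(axis=1)
        self.keep = keep_np

        xy = pd.concat(rows_xy, ignore_index=True)
        ic, jc = self.cgrid.cell_of(xy["x"].to_numpy(), xy["y"].to_numpy())
        ic = np.clip(ic, 0, self.cgrid.nx - 1)
        jc = np.clip(jc, 0, self.cgrid.ny - 1)
        tidx = xy["year"].to_numpy().astype(int) - grid.years[0]
        cell = tidx * self.n_cells + jc * self.cgrid.nx + ic
        A = sp.csr_matrix(
            (np.ones(n_rows), (np.arange(n_rows), cell)),
            shape=(n_rows, self.n_u))

        self.B = sp.hstack([sp.csr_matrix(dense), A], format="csr")[keep_np]
        self.w = np.concatenate(rows_w)[keep_np]
        self.z = np.concatenate(rows_z)[keep_np]
        self.n_coef = self.n_beta + self.n_delta
        self.n_theta = self.n_coef + self.n_u
        # fine->coarse cell replication factors for upsampling the field
        self._rep_y = np.clip((np.arange(grid.ny) // spec.coarsen), 0, self.cgrid.ny - 1)
        self._rep_x = np.clip((np.arange(grid.nx) // spec.coarsen), 0, self.cgrid.nx - 1)

    # -- penalized objective -------------------------------------------
    def precision(self, params: rf.FieldParams):
        spat = rf.spatial_precision(self.cgrid, params.rho, params.sigma)
        return rf.spacetime_precision(spat, params.phi, self.n_years)

    def neg_logpost(self, theta, Q) -> float:
        ell = np.asarray(self.B @ theta).ravel()
        like = float((self.w * np.exp(np.clip(ell, -_L_CAP, _L_CAP))).sum()
                     - ell[self.z == 1].sum())
        coef = theta[:self.n_coef]
        u = theta[self.n_coef:]
        pen = 0.5 * self.spec.prior_prec * float(coef @ coef)
        pen += 0.5 * float(u @ (Q.matrix @ u))
        return like + pen

    def grad_hess(self, theta, Q, want_hess=True):
        ell = np.asarray(self.B @ theta).ravel()
        v = self.w * np.exp(np.clip(ell, -_L_CAP, _L_CAP))
        g = self.B.T @ (v - self.z)
        g = np.asarray(g).ravel()
        g[:self.n_coef] += self.spec.prior_prec * theta[:self.n_coef]
        g[self.n_coef:] += Q.matrix @ theta[self.n_coef:]
        if not want_hess:
            return g, None
        Bw = self.B.multiply(v[:, None])
        H = (self.B.T @ Bw).tocsc()
        P = sp.block_diag([
            sp.identity(self.n_coef) * self.spec.prior_prec,
            Q.matrix], format="csc")
        return g, (H + P).tocsc()

    def newton(self, Q, theta0=None, gtol=1e-6, max_iter=50):
        theta = np.zeros(self.n_theta) if theta0 is None else theta0.copy()
        if theta0 is None:
            # homogeneous-intensity start for the intercept
            theta[0] = np.log(max(self.z.sum(), 0.5) / self.w.sum())
        f = self.neg_logpost(theta, Q)
        lu = None
        scale = max(1.0, float(self.z.sum()))
        for it in range(max_iter):
            g, H = self.grad_hess(theta, Q)
            gnorm = float(np.linalg.norm(g, np.inf))
            lu = splu(H)
            if gnorm < gtol * scale:
                return theta, f, lu, it, gnorm
            step = lu.solve(-g)
            t = 1.0
            for _ in range(30):
                f_new = self.neg_logpost(theta + t * step, Q)
                if f_new <= f + 1e-12 * abs(f):
                    break
                t *= 0.5
            else:
                raise RuntimeError(
                    f"Newton line search failed at iteration {it} "
                    f"(grad norm {gnorm:.3e})")
            theta = theta + t * step
            f = f_new
        raise RuntimeError(
            f"inner Newton did not converge in {max_iter} iterations "
            f"(grad norm {gnorm:.3e})")


def _logdet_lu(lu) -> float:
    d = lu.U.diagonal()
    return float(np.sum(np.log(np.abs(d))))


def _laplace_objective(problem: _Problem, params: rf.FieldParams,
                       theta0=None):
    Q = problem.precision(params)
    theta, f, lu, n_it, gnorm = problem.newton(Q, theta0)
    pc = problem.spec.pc_prior
    # Laplace: log p(y, theta_h) ~ -F(mode) + 1/2 log|Q| - 1/2 log|H| + priors
    # (phi prior uniform on (-1, 1); additive constants dropped)
    obj = (-f + 0.5 * Q.logdet - 0.5 * _logdet_lu(lu)
           + rf.pc_prior_logdens(params.rho, params.sigma, pc["rho0"],
                                 pc["alpha_rho"], pc["sigma0"],
                                 pc["alpha_sigma"]))
    return obj, theta, f, lu, Q, n_it, gnorm


def _to_unconstrained(p: rf.FieldParams) -> np.ndarray:
    return np.array([np.log(p.rho), np.log(p.sigma), np.arctanh(p.phi)])


def _from_unconstrained(x, min_rho: float) -> rf.FieldParams:
    rho = float(np.exp(np.clip(x[0], -30, 30)))
    return rf.FieldParams(rho=max(rho, min_rho),
                          sigma=float(np.exp(np.clip(x[1], -15, 15))),
                          phi=float(np.tanh(x[2])))


def fit(spec: ModelSpec, data, seed: int = 0, streams=("nest", "ebird"),
        x_scaler=None, z_scaler=None,
        fixed_field: rf.FieldParams | None = None) -> FitResult:
    """Fit the integrated model.

    ``data`` is a mapping with ``points`` (:class:`PointTable`) and
    ``layers``.  ``fixed_field`` (or ``spec.optimize_hyperparams=False``)
    skips the outer hyperparameter optimization and conditions on the given
    (or initial) field parameters — the fast path used by the bootstrap.
    """
    points: PointTable = data["points"]
    layers = data["layers"]
    prob = _Problem(spec, points, layers, seed, streams=streams,
                    x_scaler=x_scaler, z_scaler=z_scaler)
    min_rho = 2.0 * prob.cgrid.dx

    params = fixed_field or spec.field_init
    optimize = spec.optimize_hyperparams and fixed_field is None
    trace = []
    if optimize:
        rng = np.random.default_rng(seed)
        warm = {"theta": None}

        def negobj(x):
            p = _from_unconstrained(x, min_rho)
            try:
                obj, theta, *_ = _laplace_objective(prob, p, warm["theta"])
            except (RuntimeError, ValueError) as exc:
                logger.debug("outer objective failed at %s: %s", p, exc)
                return 1e10
            warm["theta"] = theta
            trace.append((p, obj))
            return -obj

        best = None
        x_init = _to_unconstrained(params)
        inits = [x_init]
        for _ in range(max(0, spec.n_restarts - 1)):
            inits.append(x_init + rng.normal(0, 0.3, 3))
        for x0 in inits:
            res = minimize(negobj, x0, method="Nelder-Mead",
                           options={"maxfev": spec.max_outer, "xatol": 1e-3,
                                    "fatol": 1e-4})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        params = _from_unconstrained(best.x, min_rho)

    obj, theta, f, lu, Q, n_it, gnorm = _laplace_objective(prob, params)

    # --- coefficient summaries from the Gaussian approximation ---------
    names, blocks = ["intercept_nest"], ["ecological"]
    names += prob.x_cols
    blocks += ["ecological"] * len(prob.x_cols)
    if prob.n_delta:
        names.append("intercept_ebird")
        blocks.append("observation")
        names += prob.z_cols
        blocks += ["observation"] * len(prob.z_cols)
    sds = []
    for k in range(prob.n_coef):
        e = np.zeros(prob.n_theta)
        e[k] = 1.0
        sds.append(float(np.sqrt(max(lu.solve(e)[k], 0.0))))
    est = theta[:prob.n_coef]
    zq = 1.959963984540054
    coef_df = pd.DataFrame({
        "name": names, "block": blocks, "q50": est,
        "q2.5": est - zq * np.array(sds), "q97.5": est + zq * np.array(sds),
        "sd": sds,
    })[["name", "block", "q2.5", "q50", "q97.5", "sd"]]

    # --- hyperparameter summaries --------------------------------------
    hyper = {"rho": params.rho, "sigma": params.sigma, "phi": params.phi,
             "optimized": bool(optimize)}
    if optimize:
        try:
            hyper.update(_hyper_intervals(prob, params, min_rho))
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            logger.info("hyperparameter interval computation failed: %s", exc)

    # --- field mode and sd ---------------------------------------------
    u = theta[prob.n_coef:]
    grid = spec.grid
    u3 = u.reshape(prob.n_years, prob.cgrid.ny, prob.cgrid.nx)
    field_mode = {}
    for k, yr in enumerate(grid.year_list):
        fine = u3[k][np.ix_(prob._rep_y, prob._rep_x)]
        field_mode[yr] = Raster(grid, fine)
    field_sd = None
    if spec.n_sd_probes > 0:
        rng = np.random.default_rng(seed + 7)
        acc = np.zeros(prob.n_u)
        for _ in range(spec.n_sd_probes):
            zp = rng.choice([-1.0, 1.0], prob.n_theta)
            sol = lu.solve(zp)
            acc += (zp * sol)[prob.n_coef:]
        du = np.sqrt(np.maximum(acc / spec.n_sd_probes, 0.0))
        du3 = du.reshape(prob.n_years, prob.cgrid.ny, prob.cgrid.nx).mean(axis=0)
        field_sd = Raster(grid, du3[np.ix_(prob._rep_y, prob._rep_x)])

    # Hessian conditioning diagnostic on the coefficient block
    diag_msgs = []
    cond = None
    try:
        Hc = np.empty((prob.n_coef, prob.n_coef))
        for k in range(prob.n_coef):
            e = np.zeros(prob.n_theta)
            e[k] = 1.0
            Hc[:, k] = lu.solve(e)[:prob.n_coef]
        cond = float(np.linalg.cond(Hc))
        if cond > 1e8:
            diag_msgs.append("flat direction suspected in coefficient block")
    except np.linalg.LinAlgError:
        diag_msgs.append("coefficient covariance not computable")

    diagnostics = {
        "inner_iterations": n_it,
        "grad_norm": gnorm,
        "converged": True,
        "coef_cov_condition": cond,
        "messages": diag_msgs,
        "n_rows": int(prob.keep.sum()),
        "n_dropped": int((~prob.keep).sum()),
        "streams": list(prob.streams),
    }
    return FitResult(
        coefficients=coef_df, hyperparams=hyper, field_mode=field_mode,
        field_sd=field_sd, marginal_loglik=float(obj), diagnostics=diagnostics,
        spec=spec, x_scaler=prob.x_scaler, z_scaler=prob.z_scaler,
        coarse_grid=prob.cgrid, u_vector=u, streams=prob.streams)


def _hyper_intervals(prob: _Problem, params: rf.FieldParams, min_rho: float,
                     h: float = 0.05) -> dict:
    """Gaussian intervals on (log rho, log sigma, atanh phi) by numeric
    differentiation of the Laplace objective, backtransformed."""
    x0 = _to_unconstrained(params)

    def obj(x):
        return _laplace_objective(prob, _from_unconstrained(x, min_rho))[0]

    n = 3
    Hm = np.zeros((n, n))
    f0 = obj(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                Hm[i, i] = (obj(x0 + ei) - 2 * f0 + obj(x0 - ei)) / h**2
            else:
                Hm[i, j] = Hm[j, i] = (
                    obj(x0 + ei + ej) - obj(x0 + ei - ej)
                    - obj(x0 - ei + ej) + obj(x0 - ei - ej)) / (4 * h**2)
    cov_m = np.linalg.inv(-Hm)
    sd = np.sqrt(np.maximum(np.diag(cov_m), 0.0))
    zq = 1.959963984540054
    lo = x0 - zq * sd
    hi = x0 + zq * sd
    return {
        "rho_ci": [float(np.exp(lo[0])), float(np.exp(hi[0]))],
        "sigma_ci": [float(np.exp(lo[1])), float(np.exp(hi[1]))],
        "phi_ci": [float(np.tanh(lo[2])), float(np.tanh(hi[2]))],
    }


def fit_without_stream(spec: ModelSpec, data, drop: str, seed: int = 0,
                       **kw) -> FitResult:
    """Refit with one stream's likelihood term removed."""
    if drop not in ("nest", "ebird"):
        raise ValueError(f"unknown stream '{drop}'")
    keep = tuple(s for s in ("nest", "ebird") if s != drop)
    points: PointTable = data["points"]
    if all(len(points.stream(s)) == 0 for s in keep):
        raise ValueError("remaining stream is empty")
    if drop == "ebird" and len(points.stream("ebird")) == 0:
        # dropping an empty stream changes nothing
        return fit(spec, data, seed=seed, streams=("nest", "ebird"), **kw)
    spec2 = ModelSpec(**{**spec.__dict__})
    if drop == "ebird":
        spec2.obs_specs = []
    return fit(spec2, data, seed=seed, streams=keep, **kw)
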