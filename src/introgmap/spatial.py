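"""First-stage spatial analysis of single field trials.

Each site x treatment trial is fitted with the fixed-effects model
``y = X tau + e`` where ``tau`` contains genotype effects (always) and
optional row / column / replicate / tester factors, and the residual
covariance is separable first-order autoregressive over the field grid
with an independent nugget:

    R = sigma2_zeta * [AR1(rho_col) (x) AR1(rho_row)] + sigma2_eta * I

Plots are ordered column-major (rows fastest within a column), which makes
``R`` the Kronecker product ``AR1(rho_col) (x) AR1(rho_row)`` plus the
nugget; the element-wise construction
``cor(a, b) = rho_row^|dRow| * rho_col^|dCol|`` is equivalent and
ordering-free.

The restricted likelihood is maximized over
``(rho_row, rho_col, lambda = sigma2_eta / sigma2_zeta)`` with
``sigma2_zeta`` profiled out analytically; the optimizer is bounded
L-BFGS-B started from a fixed 3x3x3 grid, so fits are deterministic.  On a
complete grid the Kronecker eigendecomposition gives O(R^3 + C^3) solves;
with missing plots the observed submatrix is factorized densely (rows of
the design are dropped and the covariance subsetted — conditioning, not
imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

__all__ = [
    "SpatialModelSpec",
    "StageOneFit",
    "SpatialTrialModel",
    "ar1_correlation",
    "residual_covariance",
    "fit_spatial_reml",
    "sample_variogram",
    "select_spatial_factors",
]

DENSE_PLOT_LIMIT = 10_000


@dataclass
class SpatialModelSpec:
    """Fixed terms and residual parameters of a single-trial spatial model."""

    factors: tuple = ()  # subset of {"row", "col", "rep", "tester"}
    sigma2_spatial: float = 1.0
    sigma2_nugget: float = 0.0
    rho_row: float = 0.0
    rho_col: float = 0.0

    def __post_init__(self):
        if abs(self.rho_row) >= 1 or abs(self.rho_col) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma2_spatial < 0 or self.sigma2_nugget < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class StageOneFit:
    """Per-trial REML solution: BLUEs/SEs, spatial parameters, diagnostics."""

    blues: pd.Series
    se: pd.Series
    sigma2_spatial: float
    sigma2_nugget: float
    rho_row: float
    rho_col: float
    loglik: float
    residual_grid: np.ndarray
    wald: dict
    spec: SpatialModelSpec
    boundary_flags: list = field(default_factory=list)


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho^|i-j|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def residual_covariance(spec: SpatialModelSpec, n_rows: int, n_cols: int) -> np.ndarray:
    """Dense R = sigma2_zeta * AR1(rho_col) (x) AR1(rho_row) + sigma2_eta * I.

    Plot ordering is column-major (row index fastest).  Dense construction
    is refused for grids above 10^4 plots; the fitting code uses the
    Kronecker eigendecomposition instead at that scale.
    """
    n = n_rows * n_cols
    if n > DENSE_PLOT_LIMIT:
        raise ValueError(
            f"dense covariance for {n} plots refused (limit {DENSE_PLOT_LIMIT}); "
            "use the structured solver in SpatialTrialModel"
        )
    k = np.kron(ar1_correlation(n_cols, spec.rho_col), ar1_correlation(n_rows, spec.rho_row))
    return spec.sigma2_spatial * k + spec.sigma2_nugget * np.eye(n)


# ---------------------------------------------------------------------------
# design construction


def _design(plots: pd.DataFrame, factors, entry_col="entry"):
    """Intercept + treatment-coded genotype + treatment-coded extra factors.

    Returns (X, entries, column-slices per factor, contrast matrix rows for
    genotype adjusted means).  The estimable-function convention is
    genotype mean = intercept + genotype effect, averaged over the levels
    of every other fixed factor.
    """
    entries = sorted(plots[entry_col].astype(str).unique())
    n = len(plots)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    e_index = {e: i for i, e in enumerate(entries)}
    g = plots[entry_col].astype(str).map(e_index).to_numpy()
    for e in entries[1:]:
        cols.append((g == e_index[e]).astype(float))
        names.append(f"g:{e}")
    slices = {}
    for f in factors:
        levels = sorted(plots[f].astype(str).unique())
        if len(levels) < 2:
            continue
        start = len(cols)
        lv = plots[f].astype(str).to_numpy()
        for l in levels[1:]:
            cols.append((lv == l).astype(float))
            names.append(f"{f}:{l}")
        slices[f] = (slice(start, len(cols)), len(levels))
    X = np.column_stack(cols)
    # genotype adjusted-mean contrasts
    p = X.shape[1]
    C = np.zeros((len(entries), p))
    C[:, 0] = 1.0
    for i, e in enumerate(entries):
        if i > 0:
            C[i, i] = 1.0  # genotype dummies occupy columns 1..len(entries)-1
    for f, (sl, n_levels) in slices.items():
        C[:, sl] = 1.0 / n_levels
    return X, entries, slices, C


# ---------------------------------------------------------------------------
# REML kernels


class _EigenKernel:
    """Restricted-likelihood evaluations on a complete grid via Kronecker eigen."""

    def __init__(self, y_grid, X, n_rows, n_cols):
        self.R, self.C = n_rows, n_cols
        self.y_grid = y_grid
        n, p = X.shape
        self.n, self.p = n, p
        # each design column as an R x C grid (column-major plot order)
        self.Xg = X.T.reshape(p, n_cols, n_rows).transpose(0, 2, 1)

    def quantities(self, rho_r, rho_c, lam):
        dr, Qr = np.linalg.eigh(ar1_correlation(self.R, rho_r))
        dc, Qc = np.linalg.eigh(ar1_correlation(self.C, rho_c))
        yt = (Qr.T @ self.y_grid @ Qc).flatten(order="F")
        T = np.einsum("si,psc,cj->pij", Qr, self.Xg, Qc, optimize=True)
        Xt = T.transpose(1, 2, 0).reshape(self.n, self.p, order="F")
        d = (dc[:, None] * dr[None, :]).flatten() + lam
        w = 1.0 / d
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        yWy = float(yt @ (w * yt))
        logdetC = float(np.sum(np.log(d)))
        return XtWX, XtWy, yWy, logdetC


class _DenseKernel:
    """Dense-Cholesky evaluations for incomplete grids (observed plots only)."""

    def __init__(self, y, X, rows, cols):
        self.y, self.X = y, X
        self.rows, self.cols = rows, cols  # 0-based plot coordinates
        self.n, self.p = X.shape
        if self.n > DENSE_PLOT_LIMIT:
            raise ValueError(f"{self.n} observed plots exceed the dense solver limit")
        self.dr = np.abs(rows[:, None] - rows[None, :])
        self.dc = np.abs(cols[:, None] - cols[None, :])

    def quantities(self, rho_r, rho_c, lam):
        K = (rho_r ** self.dr) * (rho_c ** self.dc) if (rho_r or rho_c) else np.eye(self.n)
        Cmat = K + lam * np.eye(self.n)
        L = cho_factor(Cmat, lower=True)
        Xi = cho_solve(L, self.X)
        yi = cho_solve(L, self.y)
        XtWX = self.X.T @ Xi
        XtWy = self.X.T @ yi
        yWy = float(self.y @ yi)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        return XtWX, XtWy, yWy, logdetC


def _reml_nll(kernel, rho_r, rho_c, lam):
    n, p = kernel.n, kernel.p
    XtWX, XtWy, yWy, logdetC = kernel.quantities(rho_r, rho_c, lam)
    sign, logdetXtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, None
    beta = np.linalg.solve(XtWX, XtWy)
    quad = yWy - float(XtWy @ beta)
    if quad <= 0:
        return np.inf, None
    s2 = quad / (n - p)
    nll = 0.5 * ((n - p) * np.log(s2) + logdetC + logdetXtWX + (n - p))
    return nll, (beta, s2, XtWX)


class SpatialTrialModel(BaseEstimator):
    """REML fit of the AR1xAR1 + nugget model for one field trial.

    Parameters
    ----------
    factors : tuple of str
        Extra fixed factors beyond genotype, from
        {"row", "col", "rep", "tester"}.
    response, entry_col : str
        Column names in the plot table.
    rho_bound : float
        Autocorrelations are constrained to (-rho_bound, rho_bound).
    n_starts : int
        Number of best grid points used to start local optimization.

    Fitted attributes (trailing underscore): ``blues_``, ``se_``,
    ``rho_row_``, ``rho_col_``, ``sigma2_spatial_``, ``sigma2_nugget_``,
    ``loglik_``, ``residual_grid_``, ``wald_``, ``boundary_flags_``.
    """

    def __init__(self, factors=(), response="yield", entry_col="entry",
                 rho_bound=0.95, n_starts=3):
        self.factors = factors
        self.response = response
        self.entry_col = entry_col
        self.rho_bound = rho_bound
        self.n_starts = n_starts

    def fit(self, plots: pd.DataFrame, y=None):
        plots = pd.DataFrame(plots)
        for c in ("row", "col", self.entry_col, self.response):
            if c not in plots.columns:
                raise ValueError(f"plot table lacks required column '{c}'")
        obs = plots[np.isfinite(plots[self.response].astype(float))].copy()
        frac = len(obs) / len(plots)
        if frac < 0.9:
            warnings.warn(f"only {frac:.0%} of plots have a yield; fit may be unstable")
        n_rows = int(plots["row"].max())
        n_cols = int(plots["col"].max())
        rows0 = obs["row"].astype(int).to_numpy() - 1
        cols0 = obs["col"].astype(int).to_numpy() - 1
        if len(set(zip(obs["row"], obs["col"]))) != len(obs):
            raise ValueError("duplicate (row, col) plot positions in trial")
        yv = obs[self.response].astype(float).to_numpy()
        X, entries, slices, Cmat = _design(obs, self.factors, self.entry_col)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("singular fixed-effects design (confounded factor)")

        complete = len(obs) == n_rows * n_cols
        if complete:
            y_grid = np.full((n_rows, n_cols), np.nan)
            y_grid[rows0, cols0] = yv
            kernel = _EigenKernel(y_grid, X, n_rows, n_cols)
        else:
            kernel = _DenseKernel(yv, X, rows0, cols0)

        b = self.rho_bound
        grid_rho = tuple(float(np.clip(r, -b, b)) for r in (0.0, 0.4, 0.8))
        grid_loglam = (np.log(0.2), 0.0, np.log(5.0))
        starts = []
        for rr in grid_rho:
            for rc in grid_rho:
                for ll in grid_loglam:
                    nll, _ = _reml_nll(kernel, rr, rc, np.exp(ll))
                    starts.append((nll, (rr, rc, ll)))
        starts.sort(key=lambda t: t[0])

        def obj(theta):
            nll, _ = _reml_nll(kernel, theta[0], theta[1], np.exp(theta[2]))
            return nll if np.isfinite(nll) else 1e10

        best = None
        for nll0, x0 in starts[: self.n_starts]:
            res = optimize.minimize(
                obj, x0=np.array(x0), method="L-BFGS-B",
                bounds=[(-b, b), (-b, b), (-14.0, 14.0)],
                options={"ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("spatial REML failed to converge from every start")
        rho_r, rho_c, loglam = best.x
        lam = float(np.exp(loglam))
        nll, aux = _reml_nll(kernel, rho_r, rho_c, lam)
        if aux is None:
            raise RuntimeError(
                f"spatial REML did not converge; best point {best.x}, |grad| unavailable"
            )
        beta, s2_spatial, XtWX = aux

        flags = []
        if abs(rho_r) > 0.999 * b or abs(rho_c) > 0.999 * b:
            flags.append("rho at boundary")
        if loglam <= -13.9:
            flags.append("nugget variance near zero")
        if loglam >= 13.9:
            flags.append("spatial variance near zero")

        cov = s2_spatial * np.linalg.inv(XtWX)
        blues = Cmat @ beta
        se = np.sqrt(np.maximum(np.einsum("ip,pq,iq->i", Cmat, cov, Cmat), 0.0))
        wald = {}
        for f, (sl, _) in slices.items():
            bf = beta[sl]
            covf = cov[sl, sl]
            try:
                stat = float(bf @ np.linalg.solve(covf, bf))
            except np.linalg.LinAlgError:
                continue
            df = len(bf)
            wald[f] = {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}

        fitted = X @ beta
        resid_grid = np.full((n_rows, n_cols), np.nan)
        resid_grid[rows0, cols0] = yv - fitted

        self.entries_ = entries
        self.blues_ = pd.Series(blues, index=entries, name="blue")
        self.se_ = pd.Series(se, index=entries, name="se")
        self.rho_row_ = float(rho_r)
        self.rho_col_ = float(rho_c)
        self.sigma2_spatial_ = float(s2_spatial)
        self.sigma2_nugget_ = float(s2_spatial * lam)
        self.loglik_ = float(-nll)
        self.residual_grid_ = resid_grid
        self.wald_ = wald
        self.boundary_flags_ = flags
        self.n_obs_ = len(obs)
        return self

    def reml_loglik(self, plots, rho_row, rho_col, sigma2_spatial, sigma2_nugget):
        """Restricted log-likelihood at fixed spatial parameters (for oracles)."""
        plots = pd.DataFrame(plots)
        obs = plots[np.isfinite(plots[self.response].astype(float))]
        yv = obs[self.response].astype(float).to_numpy()
        X, _, _, _ = _design(obs, self.factors, self.entry_col)
        kernel = _DenseKernel(
            yv, X, obs["row"].astype(int).to_numpy() - 1, obs["col"].astype(int).to_numpy() - 1
        )
        lam = sigma2_nugget / sigma2_spatial
        nll, _ = _reml_nll(kernel, rho_row, rho_col, lam)
        return -nll

    def to_stage_one_fit(self) -> StageOneFit:
        spec = SpatialModelSpec(
            factors=tuple(self.factors),
            sigma2_spatial=self.sigma2_spatial_,
            sigma2_nugget=self.sigma2_nugget_,
            rho_row=self.rho_row_,
            rho_col=self.rho_col_,
        )
        return StageOneFit(
            blues=self.blues_,
            se=self.se_,
            sigma2_spatial=self.sigma2_spatial_,
            sigma2_nugget=self.sigma2_nugget_,
            rho_row=self.rho_row_,
            rho_col=self.rho_col_,
            loglik=self.loglik_,
            residual_grid=self.residual_grid_,
            wald=self.wald_,
            spec=spec,
            boundary_flags=self.boundary_flags_,
        )


def fit_spatial_reml(plots, factors=(), response="yield", entry_col="entry") -> StageOneFit:
    """Fit one trial and return its :class:`StageOneFit`."""
    model = SpatialTrialModel(factors=factors, response=response, entry_col=entry_col)
    model.fit(plots)
    return model.to_stage_one_fit()


def sample_variogram(fit_or_grid) -> np.ndarray:
    """Sample variogram surface of the residual grid.

    Entry ``(lr, lc)`` is half the mean squared difference of residuals for
    all plot pairs at displacement ``(lr, lc)``; entry (0, 0) is 0.
    """
    grid = fit_or_grid.residual_grid if isinstance(fit_or_grid, StageOneFit) else np.asarray(fit_or_grid)
    R, C = grid.shape
    out = np.full((R, C), np.nan)
    for lr in range(R):
        for lc in range(C):
            a = grid[: R - lr or None, : C - lc or None]
            b = grid[lr:, lc:]
            d = (a - b) ** 2
            valid = np.isfinite(d)
            if valid.any():
                out[lr, lc] = 0.5 * d[valid].mean()
    out[0, 0] = 0.0
    return out


def select_spatial_factors(plots, alpha: float = 0.05, response="yield", entry_col="entry") -> SpatialModelSpec:
    """Choose row/column fixed factors by Wald tests.

    Candidate factor sets {none, row, col, row+col} are fitted; a factor is
    retained iff its Wald p-value is below ``alpha`` in the richest
    candidate fit that includes it and is estimable.  Ties resolve toward
    the simpler model (a factor is dropped unless clearly significant).
    """
    plots = pd.DataFrame(plots)
    pvals = {}
    for cand in (("row", "col"), ("row",), ("col",)):
        if all(f in pvals for f in cand):
            continue
        try:
            model = SpatialTrialModel(factors=cand, response=response, entry_col=entry_col).fit(plots)
        except np.linalg.LinAlgError:
            warnings.warn(f"candidate factors {cand} confounded with genotype; skipped")
            continue
        for f in cand:
            if f not in pvals and f in model.wald_:
                pvals[f] = model.wald_[f]["p"]
    retained = tuple(f for f in ("row", "col") if pvals.get(f, 1.0) < alpha)
    # the jointly retained set can be inestimable even when each factor is
    # estimable alone; back off to the most significant estimable subset
    final = None
    candidates = [retained]
    if len(retained) == 2:
        ordered = sorted(retained, key=lambda f: pvals[f])
        candidates += [(ordered[0],), (ordered[1],)]
    candidates.append(())
    for cand in candidates:
        try:
            final = SpatialTrialModel(factors=cand, response=response, entry_col=entry_col).fit(plots)
            retained = cand
            break
        except np.linalg.LinAlgError:
            warnings.warn(f"retained factors {cand} inestimable together; simplifying")
    spec = SpatialModelSpec(
        factors=retained,
        sigma2_spatial=final.sigma2_spatial_,
        sigma2_nugget=final.sigma2_nugget_,
        rho_row=final.rho_row_,
        rho_col=final.rho_col_,
    )
    spec.wald_pvalues = pvals
    return spec
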