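"""REML variance components, broad-sense heritability, and entry BLUP/BLUEs.

The plot-level mixed model is

    y_ijk = mu + g_i + y_j + r_k(j) + e,

with entry (g), year (y) and replication-within-year (r) random, and the
residual e either iid or carrying a separable AR1 (row) x AR1 (column)
correlation over the field grid within each year.  Variance components are
estimated by direct maximization of the restricted log-likelihood over
log-variances and atanh-correlations (Nelder-Mead with restarts, then a BFGS
polish).  Broad-sense heritability on a line-mean basis is

    single year:   H2 = s2_G / (s2_G + s2_e / r)
    multi  year:   H2 = s2_G / (s2_G + s2_GY / y + s2_e / (y r)),

with r replications and y years.  Single-year fits drop the year and
rep-within-year terms, matching the single-year formula's denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .core import VarianceComponents, rng_for

_LOGVAR_MIN, _LOGVAR_MAX = -25.0, 25.0


def _indicator(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _spatial_corr(plots: pd.DataFrame, rho_row: float, rho_col: float) -> np.ndarray:
    """Block-diagonal (per year) separable AR1 x AR1 residual correlation."""
    n = len(plots)
    C = np.zeros((n, n))
    rows = plots["row"].to_numpy(float)
    cols = plots["col"].to_numpy(float)
    years = plots["year"].to_numpy()
    for yr in np.unique(years):
        idx = np.flatnonzero(years == yr)
        dr = np.abs(rows[idx][:, None] - rows[idx][None, :])
        dc = np.abs(cols[idx][:, None] - cols[idx][None, :])
        C[np.ix_(idx, idx)] = (rho_row**dr) * (rho_col**dc)
    return C


class _ModelTerms:
    """Cached design matrices and the parameter layout for one dataset."""

    def __init__(self, plots: pd.DataFrame, spatial: str):
        if spatial not in ("iid", "ar1"):
            raise ValueError(f"spatial must be 'iid' or 'ar1', got {spatial!r}")
        required = {"entry", "year", "rep", "value"}
        if missing := required - set(plots.columns):
            raise ValueError(f"plot table missing columns: {sorted(missing)}")
        if spatial == "ar1" and not {"row", "col"} <= set(plots.columns):
            raise ValueError("spatial='ar1' needs row and col coordinates")
        plots = plots.reset_index(drop=True)
        self.plots = plots
        self.spatial = spatial
        self.y = plots["value"].to_numpy(float)
        self.n = len(plots)
        self.n_years = int(plots["year"].nunique())
        self.n_reps = int(plots.groupby("year")["rep"].nunique().max())
        self.multi_year = self.n_years > 1
        self.Zg = _indicator(plots["entry"])
        if self.Zg.shape[1] < 2:
            raise ValueError("need at least 2 entries")
        reps = plots.groupby("entry").size()
        if self.n < 3 or (reps.max() < 2 and self.Zg.shape[1] == self.n):
            raise ValueError("singular design: no replication of any entry")
        self.names = ["var_g"]
        self.grams = {"var_g": self.Zg @ self.Zg.T}
        if self.multi_year:
            self.Zy = _indicator(plots["year"])
            self.Zr = _indicator(plots["year"].astype(str) + "/" + plots["rep"].astype(str))
            gy = plots["entry"].astype(str) + "/" + plots["year"].astype(str)
            self.Zgy = _indicator(gy)
            self.names += ["var_year", "var_rep", "var_gy"]
            self.grams["var_year"] = self.Zy @ self.Zy.T
            self.grams["var_rep"] = self.Zr @ self.Zr.T
            self.grams["var_gy"] = self.Zgy @ self.Zgy.T
        self.names += ["var_e"]
        self._eye = np.eye(self.n)
        if spatial == "ar1":
            self.names += ["rho_row", "rho_col"]
            rows = plots["row"].to_numpy(float)
            cols = plots["col"].to_numpy(float)
            years = plots["year"].to_numpy()
            # integer lag matrices allow power-table lookup instead of elementwise pow
            self._dr = np.abs(rows[:, None] - rows[None, :]).astype(int)
            self._dc = np.abs(cols[:, None] - cols[None, :]).astype(int)
            self._same_year = (years[:, None] == years[None, :]).astype(float)
        self.n_var = len([n for n in self.names if n.startswith("var")])

    def unpack(self, theta: np.ndarray) -> dict[str, float]:
        vals = {}
        for k, name in enumerate(self.names):
            if name.startswith("var"):
                vals[name] = float(np.exp(np.clip(theta[k], _LOGVAR_MIN, _LOGVAR_MAX)))
            else:
                vals[name] = float(np.tanh(theta[k]))
        return vals

    def covariance(self, vals: dict[str, float]) -> np.ndarray:
        V = sum(vals[name] * gram for name, gram in self.grams.items())
        if self.spatial == "ar1":
            powr = vals["rho_row"] ** np.arange(self._dr.max() + 1)
            powc = vals["rho_col"] ** np.arange(self._dc.max() + 1)
            C = powr[self._dr] * powc[self._dc] * self._same_year
            V = V + vals["var_e"] * C
        else:
            V = V + vals["var_e"] * self._eye
        return V

    def neg_restricted_loglik(self, theta: np.ndarray) -> float:
        vals = self.unpack(theta)
        V = self.covariance(vals)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        rhs = np.column_stack([self.y, np.ones(self.n)])
        sol = cho_solve((c, low), rhs)
        Vi_y, Vi_1 = sol[:, 0], sol[:, 1]
        xvx = float(np.sum(Vi_1))
        beta = float(np.sum(Vi_y)) / xvx
        resid_quad = float(self.y @ Vi_y) - xvx * beta**2
        return 0.5 * (logdet_v + np.log(xvx) + resid_quad)


def restricted_loglik(plots: pd.DataFrame, vc: VarianceComponents, spatial: str = "iid") -> float:
    """Restricted log-likelihood of a given set of components (audit helper)."""
    terms = _ModelTerms(plots, spatial)
    theta = []
    for name in terms.names:
        v = getattr(vc, name)
        theta.append(np.log(max(v, 1e-10)) if name.startswith("var") else np.arctanh(v))
    return -terms.neg_restricted_loglik(np.array(theta))


def fit_variance_components(
    plots: pd.DataFrame, spatial: str = "iid", n_restarts: int = 3, seed: int = 0
) -> VarianceComponents:
    """REML estimates of the mixed-model variance components.

    Multi-year terms (year, rep-within-year, genotype-by-year) are included
    automatically when the table spans more than one year.  Derivative-free
    simplex search with ``n_restarts`` jittered starts, then a quasi-Newton
    polish; with an iid residual and balanced data the estimates agree with
    the classical ANOVA expected-mean-squares solutions.
    """
    terms = _ModelTerms(plots, spatial)
    vy = float(np.var(terms.y, ddof=1))
    vy = max(vy, 1e-8)
    if spatial == "ar1":
        # ladder start: solve the cheap iid problem first, add rho = 0
        vc0 = fit_variance_components(plots, spatial="iid", n_restarts=max(1, n_restarts - 1), seed=seed)
        base = [np.log(max(vc0.var_g, vy * 1e-4))]
        if terms.multi_year:
            base += [np.log(max(v, vy * 1e-4)) for v in (vc0.var_year, vc0.var_rep, vc0.var_gy)]
        base += [np.log(max(vc0.var_e, vy * 1e-4)), 0.0, 0.0]
    else:
        base = [np.log(vy / 2.0)]
        if terms.multi_year:
            base += [np.log(vy / 10.0)] * 3
        base += [np.log(vy / 2.0)]
    base = np.array(base)
    rng = rng_for(seed, 101)
    best = None
    for r in range(max(1, n_restarts)):
        x0 = base if r == 0 else base + rng.normal(0.0, 0.5, size=base.size)
        res = minimize(
            terms.neg_restricted_loglik, x0, method="Nelder-Mead",
            options={"maxiter": 250 * base.size, "xatol": 1e-6, "fatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(terms.neg_restricted_loglik, best.x, method="BFGS",
                      options={"gtol": 1e-10, "maxiter": 200})
    if polish.fun <= best.fun:
        best = polish
    vals = terms.unpack(best.x)
    converged = bool(np.isfinite(best.fun))
    return VarianceComponents(
        var_g=vals["var_g"],
        var_e=vals["var_e"],
        var_gy=vals.get("var_gy", 0.0),
        var_year=vals.get("var_year", 0.0),
        var_rep=vals.get("var_rep", 0.0),
        rho_row=vals.get("rho_row", 0.0),
        rho_col=vals.get("rho_col", 0.0),
        n_reps=terms.n_reps,
        n_years=terms.n_years,
        loglik=-float(best.fun),
        converged=converged,
    )


def heritability(vc: VarianceComponents, mode: str = "single_year") -> float:
    """Broad-sense heritability on a line-mean basis from fitted components."""
    r, y = vc.n_reps, vc.n_years
    if r < 1:
        raise ValueError("need at least one replication")
    if mode == "single_year":
        denom = vc.var_g + vc.var_e / r
    elif mode == "multi_year":
        if y < 1:
            raise ValueError("multi_year mode needs at least one year")
        denom = vc.var_g + vc.var_gy / y + vc.var_e / (y * r)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    return float(vc.var_g / denom)


def entry_values(
    plots: pd.DataFrame,
    mode: str = "BLUP",
    vc: VarianceComponents | None = None,
    spatial: str = "iid",
) -> pd.Series:
    """Per-entry BLUPs (shrunken random-entry predictions) or BLUEs (fixed-entry
    generalized least squares), both under the fitted residual structure.

    BLUEs regress on entry indicators with the non-genetic covariance in the
    GLS weight, so balanced iid data yields arithmetic entry means.  BLUPs are
    mu + s2_G * Zg' V^{-1} (y - mu) and shrink toward the grand mean.
    """
    if vc is None:
        vc = fit_variance_components(plots, spatial=spatial)
    terms = _ModelTerms(plots, spatial)
    entries = pd.factorize(terms.plots["entry"])[1]
    vals = {
        "var_g": vc.var_g, "var_e": max(vc.var_e, 1e-10), "var_year": vc.var_year,
        "var_rep": vc.var_rep, "var_gy": vc.var_gy, "rho_row": vc.rho_row, "rho_col": vc.rho_col,
    }
    if mode == "BLUE":
        V0 = terms.covariance({**vals, "var_g": 0.0})
        X = terms.Zg
        Vi_X = np.linalg.solve(V0, X)
        beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ terms.y)
        return pd.Series(beta, index=entries, name="blue")
    if mode == "BLUP":
        V = terms.covariance(vals)
        ones = np.ones((terms.n, 1))
        Vi_y = np.linalg.solve(V, terms.y)
        Vi_1 = np.linalg.solve(V, ones)
        mu = float((ones.T @ Vi_y).item()) / float((ones.T @ Vi_1).item())
        u = vc.var_g * (terms.Zg.T @ np.linalg.solve(V, terms.y - mu))
        return pd.Series(mu + u, index=entries, name="blup")
    raise ValueError(f"mode must be 'BLUP' or 'BLUE', got {mode!r}")
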