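"""Per-plot logistic phenology: heading date and rate of heading.

A plot's percent-heading trajectory is modeled as

    y_i = phi1 / (1 + exp(-(phi2 + phi3 * day_i)))

with the asymptote phi1 fixed at 100 (maximum percent heading).  phi2 is the
unitless intercept, phi3 the per-day slope.  Heading date is the day where the
fitted curve crosses 50% (grid search at 0.1-day increments, equal to the
closed form -phi2/phi3 when it lies in range), and the rate of heading is the
slope phi3.  Before fitting, the series is anchored with 0% points at 10, 20
and 30 days before the first observation and 100% points at 10, 20 and 30
days after the last one, stabilizing the fit for plots observed over a short
window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import AgreementStats, LogisticFit, ScoreSeries

ANCHOR_OFFSETS = (10.0, 20.0, 30.0)
DEFAULT_STEP = 0.1


def augment_anchors(series: ScoreSeries) -> ScoreSeries:
    """Add the six asymptote anchor points and return a day-sorted series."""
    if len(series) == 0:
        raise ValueError("cannot anchor an empty series")
    first, last = series.days.min(), series.days.max()
    days = np.concatenate(
        [series.days, [first - o for o in ANCHOR_OFFSETS], [last + o for o in ANCHOR_OFFSETS]]
    )
    pcts = np.concatenate([series.percents, [0.0] * 3, [100.0] * 3])
    order = np.argsort(days, kind="stable")
    return ScoreSeries(plot=series.plot, days=days[order], percents=pcts[order], source=series.source)


def _logistic(phi2: float, phi3: float, day: np.ndarray) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-(phi2 + phi3 * day)))


def _initial_guess(days: np.ndarray, pcts: np.ndarray) -> tuple[float, float]:
    # slope of logit(p) on day, with percents clipped into (0, 100) for the logit only
    p = np.clip(pcts, 1.0, 99.0) / 100.0
    z = np.log(p / (1.0 - p))
    A = np.vstack([np.ones_like(days), days]).T
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    phi3 = max(float(coef[1]), 1e-3)
    mid_day = days[np.argmin(np.abs(pcts - 50.0))]
    return -phi3 * float(mid_day), phi3


def fit_logistic(series: ScoreSeries, max_iter: int = 200, tol: float = 1e-8) -> LogisticFit:
    """Nonlinear least squares for (phi2, phi3) with phi1 fixed at 100.

    Uses Levenberg-Marquardt from a logit-regression starting point.  A fit
    that fails to converge is returned flagged, not raised; a degenerate
    series (all 0% or all 100%) is an error since the curve is unidentified.
    """
    days = series.days.astype(float)
    pcts = series.percents.astype(float)
    if np.unique(days).size < 3:
        raise ValueError("need observations on at least 3 distinct days")
    if pcts.max() == 0.0 or pcts.min() == 100.0:
        raise ValueError(f"degenerate series for plot {series.plot}: no rise through 50%")
    mid_day = float(days[np.argmin(np.abs(pcts - 50.0))])
    starts = [np.array(_initial_guess(days, pcts))]
    # fallback starts at typical wheat heading slopes, anchored at the day nearest 50%
    starts += [np.array([-p3 * mid_day, p3]) for p3 in (0.3, 0.7)]
    best = None
    for x0 in starts:
        res = least_squares(
            lambda p: _logistic(p[0], p[1], days) - pcts,
            x0,
            method="lm",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_iter * 4,
        )
        # accept when the solver reports success, or when it ran out of budget
        # at a point that is already first-order optimal (steep curves can
        # leave LM polishing a flat SSE valley)
        sse = float(np.sum(res.fun**2))
        at_optimum = res.status == 0 and (float(np.abs(res.grad).max()) < 1e-4 or sse < 1e-6)
        ok = bool((res.success or at_optimum) and np.isfinite(res.x).all())
        if best is None or (ok, -sse) > (best[1], -best[2]):
            best = (res.x, ok, sse)
        if ok:
            break
    x, ok, sse = best
    return LogisticFit(
        phi2=float(x[0]),
        phi3=float(x[1]),
        sse=sse,
        converged=ok,
        n_obs=len(series),
    )


def heading_date(
    fit: LogisticFit,
    day_range: tuple[float, float],
    step: float = DEFAULT_STEP,
) -> float:
    """Day (1 decimal) whose predicted percent heading is closest to 50%.

    Grid search over ``day_range`` at ``step`` increments; the first minimizer
    wins ties.  Agrees with the closed form -phi2/phi3 to within step/2 when
    the intersect lies inside the range.
    """
    if not fit.converged:
        raise ValueError("cannot extract heading date from a non-converged fit")
    if fit.phi3 <= 0:
        raise ValueError(f"phi3 = {fit.phi3} <= 0: curve never rises through 50%")
    lo, hi = day_range
    grid = np.arange(lo, hi + step / 2.0, step)
    pred = fit.predict(grid)
    return float(np.round(grid[np.argmin(np.abs(pred - 50.0))], 1))


def heading_rate(fit: LogisticFit) -> float:
    """Rate of heading: the slope phi3 of the fitted logistic (percent progression per day)."""
    if not fit.converged:
        raise ValueError("cannot extract rate from a non-converged fit")
    return float(fit.phi3)


def fit_plots(scores: pd.DataFrame, step: float = DEFAULT_STEP, anchors: bool = True) -> pd.DataFrame:
    """Fit every plot in a (plot, day, percent) table.

    Returns one row per plot with phi2, phi3, heading_date, rate, converged,
    sse and n_obs.  Plots whose fit does not converge get NaN dates but are
    kept (flagged) so downstream joins stay aligned.
    """
    rows = []
    for plot, grp in scores.groupby("plot", sort=False):
        series = ScoreSeries(
            plot=str(plot),
            days=grp["day"].to_numpy(dtype=float),
            percents=grp["percent"].to_numpy(dtype=float),
            source=str(grp["source"].iloc[0]) if "source" in grp else "visual",
        )
        if anchors:
            series = augment_anchors(series)
        fit = fit_logistic(series)
        if fit.converged and fit.phi3 > 0:
            hd = heading_date(fit, (series.days.min(), series.days.max()), step=step)
            rate = heading_rate(fit)
        else:
            hd, rate = np.nan, np.nan
        rows.append(
            {
                "plot": plot,
                "phi2": fit.phi2,
                "phi3": fit.phi3,
                "heading_date": hd,
                "rate": rate,
                "converged": fit.converged,
                "sse": fit.sse,
                "n_obs": fit.n_obs,
            }
        )
    return pd.DataFrame(rows)


def series_agreement(dates_a: pd.Series, dates_b: pd.Series) -> AgreementStats:
    """Agreement statistics between two per-plot heading-date measurements.

    Both inputs are indexed by plot and must cover the same plots.  The slope
    is the least-squares regression (with intercept) of method B on method A.
    """
    a, b = pd.Series(dates_a).astype(float), pd.Series(dates_b).astype(float)
    if len(a) < 2:
        raise ValueError("need at least 2 plots")
    if set(a.index) != set(b.index):
        raise ValueError("plot sets differ between the two measurements")
    b = b.reindex(a.index)
    diff = (b - a).to_numpy()
    A = np.vstack([np.ones(len(a)), a.to_numpy()]).T
    slope = float(np.linalg.lstsq(A, b.to_numpy(), rcond=None)[0][1])
    return AgreementStats(
        mae=float(np.mean(np.abs(diff))),
        rmse=float(np.sqrt(np.mean(diff**2))),
        frac_within_1=float(np.mean(np.abs(diff) <= 1.0)),
        frac_within_2=float(np.mean(np.abs(diff) <= 2.0)),
        slope=slope,
        n=len(a),
    )
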