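"""Cox modelling of factors associated with high-dose use.

Continuous covariates enter as restricted cubic splines (Harrell
truncated-power basis, knots at standard sample quantiles, natural — i.e.
linear — beyond the boundary knots).  Ties are handled by Efron's method by
default; the variance defaults to the robust (sandwich) estimator, under
which coefficients are read as time-averaged log hazard ratios when hazards
are non-proportional.  Proportionality is assessed with the Grambsch and
Therneau score test on scaled Schoenfeld residuals, and time-dependent
coefficients beta(t) are estimated by smoothing those residuals over event
time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelSpec
from .errors import ConvergenceError, DataError

#: standard knot-placement quantiles by number of knots (df = knots - 1)
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.18333, 0.34167, 0.50, 0.65833, 0.81667, 0.975),
}


@dataclass
class RCSBasis:
    """Restricted cubic spline basis: df columns, the first being x itself."""

    knots: np.ndarray
    df: int

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = len(t)
        norm = (t[-1] - t[0]) ** 2
        cols = [x]

        def pos3(v):
            return np.clip(v, 0, None) ** 3

        for j in range(k - 2):
            term = (
                pos3(x - t[j])
                - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            )
            cols.append(term / norm)
        return np.column_stack(cols)


def rcs_basis(x, df: int) -> RCSBasis:
    """Restricted cubic spline basis with ``df`` degrees of freedom
    (``df + 1`` knots at the standard quantiles of ``x``).

    Raises a :class:`DataError` suggesting a lower df when ``x`` has fewer
    than ``df + 2`` distinct values.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n_knots = df + 1
    if n_knots not in KNOT_QUANTILES:
        raise DataError(f"df={df}: supported spline df are "
                        f"{sorted(q - 1 for q in KNOT_QUANTILES)}")
    distinct = np.unique(x)
    if len(distinct) < df + 2:
        raise DataError(
            f"only {len(distinct)} distinct values for a df={df} spline; "
            f"use a lower df"
        )
    knots = np.quantile(x, KNOT_QUANTILES[n_knots])
    knots = np.unique(knots)
    if len(knots) < n_knots:
        raise DataError(
            f"knot quantiles coincide for df={df}; use a lower df"
        )
    return RCSBasis(knots=knots, df=df)


@dataclass
class DesignInfo:
    columns: list
    spline_bases: Mapping[str, RCSBasis]
    spline_refs: Mapping[str, float]
    dropped_terms: list


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, DesignInfo, int]:
    """Model matrix per the ModelSpec; complete-case rows only.

    Returns (X, design info, n_dropped_missing).  Constant columns (for
    example a covariate identically zero in this cohort) are excluded and
    recorded in ``dropped_terms``.  A spline term whose covariate has too
    few distinct values for the requested df is degraded to the largest
    feasible df (down to a plain linear term) with a warning.
    """
    used = list(spec.binary_covariates) + list(spec.categorical_covariates) + list(
        spec.spline_covariates
    )
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise DataError(f"covariates not found in data: {missing_cols}")
    sub = data[used].copy()
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    sub = sub.loc[complete]

    cols = {}
    dropped = []
    for name in spec.binary_covariates:
        v = sub[name].astype(float)
        if v.nunique() <= 1:
            dropped.append(name)
            continue
        cols[name] = v.to_numpy()
    for name, ref in spec.categorical_covariates.items():
        levels = [l for l in pd.unique(sub[name]) if l != ref]
        for level in sorted(map(str, levels)):
            cols[f"{name}[{level}]"] = (sub[name].astype(str) == level).astype(float).to_numpy()
    bases, refs = {}, {}
    for name, df_req in spec.spline_covariates.items():
        x = sub[name].astype(float).to_numpy()
        n_distinct = len(np.unique(x))
        basis = None
        for df_eff in range(df_req, 2, -1):
            try:
                basis = rcs_basis(x, df_eff)
                break
            except DataError:
                continue
        if basis is None:
            if n_distinct <= 1:
                dropped.append(name)
                continue
            warnings.warn(
                f"{name}: {n_distinct} distinct values; entering linearly "
                f"instead of as a df={df_req} spline",
                stacklevel=2,
            )
            cols[f"{name}_rcs1"] = x
            refs[name] = float(np.median(x))
            continue
        if df_eff != df_req:
            warnings.warn(
                f"{name}: df reduced {df_req} -> {df_eff} "
                f"({n_distinct} distinct values)",
                stacklevel=2,
            )
        B = basis.transform(x)
        for j in range(B.shape[1]):
            cols[f"{name}_rcs{j + 1}"] = B[:, j]
        bases[name] = basis
        refs[name] = float(np.median(x))
    X = pd.DataFrame(cols, index=sub.index)
    info = DesignInfo(
        columns=list(X.columns),
        spline_bases=bases,
        spline_refs=refs,
        dropped_terms=dropped,
    )
    return X, info, n_dropped


@dataclass
class CoxFit:
    """Fitted Cox model with both covariance estimates and fit metadata."""

    coefficients: pd.Series
    covariance_robust: pd.DataFrame
    covariance_model: pd.DataFrame
    loglik: float
    n_used: int
    n_events: int
    n_dropped_missing: int
    ties_method: str
    variance: str
    design_info: DesignInfo
    _training: pd.DataFrame = field(repr=False, default=None)

    @property
    def covariance(self) -> pd.DataFrame:
        return (
            self.covariance_robust
            if self.variance == "robust"
            else self.covariance_model
        )

    def hr_with_ci(self) -> pd.DataFrame:
        """HR with 95% CI for every non-spline term (exp of coef +/- 1.96 SE,
        SE from the configured covariance)."""
        se = np.sqrt(np.diag(self.covariance))
        terms = [
            t for t in self.coefficients.index if "_rcs" not in t
        ]
        rows = []
        for t in terms:
            b = self.coefficients[t]
            s = se[list(self.coefficients.index).index(t)]
            rows.append(
                (t, np.exp(b), np.exp(b - 1.96 * s), np.exp(b + 1.96 * s), s)
            )
        return pd.DataFrame(rows, columns=["term", "hr", "ci_low", "ci_high", "se"])


def _breslow_newton(X, time, event, tol=1e-8, max_iter=60):
    """Newton-Raphson maximiser of the Breslow-ties partial likelihood.

    Returns (beta, model covariance, robust covariance, loglik).
    """
    n, p = X.shape
    order = np.argsort(time, kind="mergesort")
    X, time, event = X[order], time[order], event[order]
    # risk set for subject i: all j with time_j >= time_i
    first_at = np.searchsorted(time, time, side="left")

    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        theta = np.exp(eta)
        S0 = np.cumsum(theta[::-1])[::-1]
        S1 = np.cumsum((theta[:, None] * X)[::-1], axis=0)[::-1]
        S2 = np.cumsum((theta[:, None, None] * X[:, :, None] * X[:, None, :])[::-1],
                       axis=0)[::-1]
        ev = event.astype(bool)
        idx = first_at[ev]
        ll = float(np.sum(eta[ev] - np.log(S0[idx])))
        xbar = S1[idx] / S0[idx, None]
        grad = np.sum(X[ev] - xbar, axis=0)
        H = -(
            np.sum(S2[idx] / S0[idx, None, None], axis=0)
            - xbar.T @ xbar
        )
        if np.linalg.norm(grad) < tol and ll >= ll_old - 1e-12:
            break
        step = np.linalg.solve(-H, grad)
        # step-halving
        scale = 1.0
        while scale > 1e-6:
            cand = beta + scale * step
            eta_c = X @ cand
            S0_c = np.cumsum(np.exp(eta_c)[::-1])[::-1]
            ll_c = float(np.sum(eta_c[ev] - np.log(S0_c[idx])))
            if ll_c > ll or np.linalg.norm(grad) < tol:
                break
            scale /= 2
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 20:
            j = int(np.argmax(np.abs(beta)))
            raise ConvergenceError(
                f"monotone partial likelihood (separation) for covariate index {j}"
            )
        ll_old = ll
    else:
        raise ConvergenceError(
            f"Breslow Newton did not converge; |grad| = {np.linalg.norm(grad):.3e}"
        )
    cov_model = np.linalg.inv(-H)
    cov_robust = _sandwich_covariance(X, time, event, beta, cov_model)
    return beta, cov_model, cov_robust, ll


def _sandwich_covariance(X, time, event, beta, A_inv):
    """Robust covariance A^-1 B A^-1 with B from per-subject score residuals
    (Breslow form of the at-risk averages).  Inputs must be sorted by time.

    U_i = delta_i (x_i - xbar(t_i))
          - theta_i * sum_{event times t_k <= t_i} (x_i - xbar(t_k)) / S0(t_k)
    """
    theta = np.exp(X @ beta)
    S0 = np.cumsum(theta[::-1])[::-1]
    S1 = np.cumsum((theta[:, None] * X)[::-1], axis=0)[::-1]
    first_at = np.searchsorted(time, time, side="left")
    ev = event.astype(bool)
    idx = first_at[ev]
    xbar_ev = S1[idx] / S0[idx, None]  # d x p, at event times
    ev_times = time[ev]
    inv_S0 = 1.0 / S0[idx]
    cum_inv = np.concatenate([[0.0], np.cumsum(inv_S0)])
    cum_xbar = np.vstack(
        [np.zeros(X.shape[1]), np.cumsum(xbar_ev * inv_S0[:, None], axis=0)]
    )
    pos = np.searchsorted(ev_times, time, side="right")
    U = -theta[:, None] * (X * cum_inv[pos, None] - cum_xbar[pos])
    U[ev] += X[ev] - xbar_ev
    B = U.T @ U
    return A_inv @ B @ A_inv


def fit_cox(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    duration_col: str = "time_days",
    event_col: str = "event",
) -> CoxFit:
    """Fit the Cox model defined by ``spec`` on time-to-event records carrying
    the covariate columns.

    Efron ties (default) are fitted with lifelines' Newton solver; the
    robust covariance is the sandwich over per-subject score residuals.  The
    Breslow option uses the package's own Newton maximiser.  Separation or
    non-convergence raises :class:`ConvergenceError`.
    """
    spec = spec or ModelSpec()
    X, info, n_dropped = build_design_matrix(records, spec)
    y = records.loc[X.index, [duration_col, event_col]]
    n_events = int(y[event_col].sum())
    if n_events < 2:
        raise DataError("fit_cox requires at least 2 events")

    if spec.ties_method == "breslow":
        beta, cov_m, cov_r, ll = _breslow_newton(
            X.to_numpy(dtype=float),
            y[duration_col].to_numpy(dtype=float),
            y[event_col].to_numpy(dtype=int),
        )
        coefs = pd.Series(beta, index=X.columns)
        cov_model = pd.DataFrame(cov_m, index=X.columns, columns=X.columns)
        cov_robust = pd.DataFrame(cov_r, index=X.columns, columns=X.columns)
        loglik = ll
        training = pd.concat([X, y], axis=1)
    else:
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError as LLConvergenceError

        training = pd.concat([X, y], axis=1)
        try:
            plain = CoxPHFitter()
            plain.fit(training, duration_col=duration_col, event_col=event_col)
        except LLConvergenceError as exc:
            raise ConvergenceError(str(exc)) from exc
        coefs = plain.params_.copy()
        cov_model = plain.variance_matrix_.copy()
        order = np.argsort(y[duration_col].to_numpy(), kind="mergesort")
        cov_r = _sandwich_covariance(
            X.to_numpy(dtype=float)[order],
            y[duration_col].to_numpy(dtype=float)[order],
            y[event_col].to_numpy(dtype=int)[order],
            coefs.to_numpy(),
            cov_model.to_numpy(),
        )
        cov_robust = pd.DataFrame(cov_r, index=X.columns, columns=X.columns)
        loglik = float(plain.log_likelihood_)

    return CoxFit(
        coefficients=coefs,
        covariance_robust=cov_robust,
        covariance_model=cov_model,
        loglik=loglik,
        n_used=len(X),
        n_events=n_events,
        n_dropped_missing=n_dropped,
        ties_method=spec.ties_method,
        variance=spec.variance,
        design_info=info,
        _training=training,
    )


def _schoenfeld_residuals(fit: CoxFit, duration_col="time_days", event_col="event"):
    """Raw Schoenfeld residuals x_i - xbar(t_i) at each event, Breslow form,
    plus the event times (ascending)."""
    df = fit._training
    cols = list(fit.coefficients.index)
    X = df[cols].to_numpy(dtype=float)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    order = np.argsort(time, kind="mergesort")
    X, time, event = X[order], time[order], event[order]
    theta = np.exp(X @ fit.coefficients.to_numpy())
    S0 = np.cumsum(theta[::-1])[::-1]
    S1 = np.cumsum((theta[:, None] * X)[::-1], axis=0)[::-1]
    first_at = np.searchsorted(time, time, side="left")
    ev = event.astype(bool)
    idx = first_at[ev]
    resid = X[ev] - S1[idx] / S0[idx, None]
    return resid, time[ev]


@dataclass
class PHDiagnostics:
    per_covariate: pd.DataFrame  # term, chi_square, p
    global_chi_square: float
    global_p: float
    global_df: int
    time_transform: str
    beta_t: Mapping[str, pd.DataFrame]  # term -> (time, beta, lo, hi)


def ph_diagnostics(
    fit: CoxFit,
    time_transform: str = "km",
    smoother_frac: float = 0.75,
) -> PHDiagnostics:
    """Grambsch-Therneau proportionality test and smoothed beta(t) curves.

    The score test regresses scaled Schoenfeld residuals on transformed
    event time g(t) (KM transform by default, as in standard survival
    software; ``identity`` and ``rank`` also supported).  With centred
    c_k = g(t_k) - mean(g), d events, model covariance V and
    u = sum_k c_k * s_k (raw residuals s_k):

        per-covariate  z_j = d * (V u)_j^2 / (V_jj * sum c^2),   1 df
        global         z   = d * u' V u / sum c^2,               p df

    beta(t) curves are lowess smooths of the scaled residuals
    d * V * s_k + beta_hat over event time, with a pointwise normal band
    from the local residual spread.
    """
    if fit.n_events < 10:
        raise DataError("ph_diagnostics requires >= 10 events")
    p = len(fit.coefficients)
    if fit.n_events <= p:
        raise DataError("fewer events than covariates")

    resid, ev_times = _schoenfeld_residuals(fit)
    d = len(ev_times)

    if time_transform == "identity":
        g = ev_times.astype(float)
    elif time_transform == "rank":
        g = stats.rankdata(ev_times, method="average")
    elif time_transform == "km":
        from lifelines import KaplanMeierFitter

        df = fit._training
        kmf = KaplanMeierFitter()
        kmf.fit(df["time_days"], df["event"])
        g = 1.0 - kmf.survival_function_at_times(ev_times).to_numpy()
    else:
        raise DataError(f"unknown time_transform {time_transform!r}")

    c = g - g.mean()
    ssc = float(np.sum(c**2))
    V = fit.covariance_model.to_numpy()
    u = resid.T @ c
    Vu = V @ u
    z = d * Vu**2 / (np.diag(V) * ssc)
    pvals = stats.chi2.sf(z, 1)
    global_z = float(d * u @ Vu / ssc)
    global_p = float(stats.chi2.sf(global_z, p))
    per = pd.DataFrame(
        {"term": list(fit.coefficients.index), "chi_square": z, "p": pvals}
    )

    # smoothed time-varying coefficients
    from statsmodels.nonparametric.smoothers_lowess import lowess

    scaled = d * (resid @ V) + fit.coefficients.to_numpy()
    curves = {}
    for j, term in enumerate(fit.coefficients.index):
        y = scaled[:, j]
        sm = lowess(y, ev_times, frac=smoother_frac, return_sorted=True)
        t_grid, b = sm[:, 0], sm[:, 1]
        interp = np.interp(ev_times, t_grid, b)
        sd = float(np.std(y - interp, ddof=1)) if d > 2 else 0.0
        half = 1.96 * sd / np.sqrt(max(d * smoother_frac, 1.0))
        curves[term] = pd.DataFrame(
            {"time": t_grid, "beta": b, "lo": b - half, "hi": b + half}
        )
    return PHDiagnostics(
        per_covariate=per,
        global_chi_square=global_z,
        global_p=global_p,
        global_df=p,
        time_transform=time_transform,
        beta_t=curves,
    )


def spline_curve(fit: CoxFit, name: str, grid=None) -> pd.DataFrame:
    """HR-versus-x curve for a spline covariate, relative to its reference
    value (the covariate median); HR is exactly 1 at the reference."""
    info = fit.design_info
    ref = info.spline_refs[name]
    terms = [t for t in fit.coefficients.index if t.startswith(f"{name}_rcs")]
    if not terms:
        raise DataError(f"{name}: no spline terms in the fit")
    if name in info.spline_bases:
        basis = info.spline_bases[name]
        if grid is None:
            k = basis.knots
            grid = np.linspace(k[0], k[-1], 101)
        B = basis.transform(np.asarray(grid, dtype=float))
        B_ref = basis.transform(np.array([ref]))
    else:  # degraded to linear
        if grid is None:
            grid = np.linspace(ref - 2, ref + 2, 101)
        B = np.asarray(grid, dtype=float)[:, None]
        B_ref = np.array([[ref]])
    delta = B - B_ref
    beta = fit.coefficients[terms].to_numpy()
    V = fit.covariance.loc[terms, terms].to_numpy()
    eta = delta @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, V, delta))
    return pd.DataFrame(
        {
            "x": np.asarray(grid, dtype=float),
            "hr": np.exp(eta),
            "lo": np.exp(eta - 1.96 * se),
            "hi": np.exp(eta + 1.96 * se),
        }
    )


def report_factors(
    fit: CoxFit, diagnostics: PHDiagnostics | None = None
) -> dict:
    """Machine-readable forest table plus per-spline HR curves."""
    forest = fit.hr_with_ci()
    if diagnostics is not None:
        forest = forest.merge(
            diagnostics.per_covariate.rename(columns={"p": "ph_p"})[
                ["term", "ph_p"]
            ],
            on="term",
            how="left",
        )
    curves = {}
    for name in fit.design_info.spline_refs:
        curves[name] = spline_curve(fit, name)
    return {"forest": forest, "spline_curves": curves}
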