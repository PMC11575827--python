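"""Growth-curve modelling: penalized-spline mixed models of age.

Fits y ~ 1 + s(age) + (1 | subject): a cubic B-spline smooth of age
(default basis dimension 10, knots at age quantiles, exact integrated
squared second-derivative penalty) plus a per-subject random intercept.
The penalty is handled through its mixed-model representation — the
smooth's penalized (wiggly) part becomes a random-effect block whose
variance is estimated alongside the subject-intercept variance by REML —
so the smoothing parameter is lambda = sigma^2 / sigma_smooth^2.
Outputs are the fitted population curve with a pointwise 95% band and
the analytic first derivative (rate of change) on a 0.2-week age grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

GRID_STEP = 0.2  # weeks; 1/5th-week resolution of curves and derivatives


@dataclass
class SplineBasis:
    """Cubic B-spline basis with its penalized-part reparameterization."""

    knots: np.ndarray
    degree: int
    center: float  # age centering for the fixed linear term
    transform: np.ndarray  # (df, df-2) maps basis coefs of the wiggly part
    df: int

    def design(self, ages: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Raw basis (or derivative) design matrix, (n, df)."""
        ages = np.asarray(ages, dtype=float)
        cols = np.empty((ages.size, self.df))
        for j in range(self.df):
            coef = np.zeros(self.df)
            coef[j] = 1.0
            sp = BSpline(self.knots, coef, self.degree, extrapolate=True)
            if deriv:
                sp = sp.derivative(deriv)
            cols[:, j] = sp(ages)
        return cols

    def fixed(self, ages: np.ndarray, deriv: int = 0) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if deriv == 0:
            return np.column_stack([np.ones_like(ages), ages - self.center])
        if deriv == 1:
            return np.column_stack([np.zeros_like(ages), np.ones_like(ages)])
        return np.zeros((ages.size, 2))

    def wiggly(self, ages: np.ndarray, deriv: int = 0) -> np.ndarray:
        return self.design(ages, deriv) @ self.transform


def bspline_basis(ages: np.ndarray, eval_ages: np.ndarray, df: int = 10) -> tuple[np.ndarray, SplineBasis]:
    """Build the quantile-knot cubic basis and evaluate it (unpenalized)."""
    basis = _make_basis(np.asarray(ages, dtype=float), df)
    return basis.design(np.asarray(eval_ages, dtype=float)), basis


def _make_basis(ages: np.ndarray, df: int) -> SplineBasis:
    k = 3
    uniq = np.unique(ages)
    df = min(df, uniq.size)  # rank guard; reduced silently only to data support
    if df < 4:
        raise ValueError("need at least 4 distinct ages for a cubic spline")
    n_interior = df - (k + 1)
    lo, hi = ages.min(), ages.max()
    if hi <= lo:
        raise ValueError("ages must span a positive range")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(ages, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])

    S = _penalty_matrix(t, k, df)
    evals, evecs = np.linalg.eigh(S)
    # null space of the second-derivative penalty is {constant, linear}
    pos = evals > max(evals.max(), 1.0) * 1e-9
    transform = evecs[:, pos] / np.sqrt(evals[pos])[None, :]
    return SplineBasis(knots=t, degree=k, center=float(ages.mean()), transform=transform, df=df)


def _penalty_matrix(t: np.ndarray, k: int, df: int) -> np.ndarray:
    """Exact integral of products of second derivatives (2-pt Gauss)."""
    spans = [(t[i], t[i + 1]) for i in range(len(t) - 1) if t[i + 1] > t[i]]
    gx, gw = np.polynomial.legendre.leggauss(2)
    S = np.zeros((df, df))
    basis2 = []
    for j in range(df):
        coef = np.zeros(df)
        coef[j] = 1.0
        basis2.append(BSpline(t, coef, k).derivative(2))
    for a, b in spans:
        x = 0.5 * (b - a) * gx + 0.5 * (a + b)
        w = 0.5 * (b - a) * gw
        D = np.column_stack([sp(x) for sp in basis2])
        S += (D * w[:, None]).T @ D
    return S


@dataclass
class TrajectoryFit:
    """A fitted spline-mixed-model growth curve."""

    basis: SplineBasis
    coef: np.ndarray  # joint (fixed, wiggly, subject) coefficients
    cov_unscaled: np.ndarray  # (q, q); multiply by sigma2 for posterior cov
    sigma2: float
    sigma2_smooth: float
    sigma2_subject: float
    lam: float  # smoothing parameter sigma2 / sigma2_smooth
    subjects: np.ndarray
    age_range: tuple[float, float]
    grid: np.ndarray
    fitted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    derivative: np.ndarray
    converged: bool

    @property
    def n_wiggly(self) -> int:
        return self.basis.transform.shape[1]


def fit_gamm(
    y: np.ndarray,
    ages: np.ndarray,
    subject_ids: np.ndarray,
    basis_dim: int = 10,
    grid: np.ndarray | None = None,
    lambda_smooth: float | None = None,
    ci_level: float = 0.95,
) -> TrajectoryFit:
    """Fit y ~ 1 + s(age) + (1 | subject) by REML.

    Parameters
    ----------
    y, ages, subject_ids : aligned per-session arrays.
    basis_dim : spline basis dimension (10 by default).
    grid : evaluation ages; defaults to the data range at 0.2-week steps.
    lambda_smooth : fix the smoothing parameter instead of estimating it
        (lambda -> infinity recovers the best-fit line).
    """
    y = np.asarray(y, dtype=float).ravel()
    ages = np.asarray(ages, dtype=float).ravel()
    subject_ids = np.asarray(subject_ids).ravel()
    ok = np.isfinite(y)
    y, ages, subject_ids = y[ok], ages[ok], subject_ids[ok]
    N = y.size
    if N < basis_dim + 5:
        raise ValueError("too few sessions for the requested basis dimension")

    basis = _make_basis(ages, basis_dim)
    X = basis.fixed(ages)
    Zs = basis.wiggly(ages)
    labels, sub_idx = np.unique(subject_ids, return_inverse=True)
    G = labels.size
    Zu = np.zeros((N, G))
    Zu[np.arange(N), sub_idx] = 1.0
    p = X.shape[1]
    ks = Zs.shape[1]

    def criterion(log_thetas):
        th_s, th_u = np.exp(log_thetas)
        V0 = np.eye(N) + th_s * (Zs @ Zs.T) + th_u * (Zu @ Zu.T)
        try:
            c, low = cho_factor(V0)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV = 2 * np.log(np.diag(c)).sum()
        Vi_X = cho_solve((c, low), X)
        Vi_y = cho_solve((c, low), y)
        A = X.T @ Vi_X
        sgn, logdetA = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ cho_solve((c, low), r))
        if quad <= 0:
            return np.inf
        return logdetV + logdetA + (N - p) * np.log(quad)

    if lambda_smooth is None:
        best = None
        for start in ([0.0, 0.0], [3.0, -3.0], [-3.0, 3.0]):
            res = optimize.minimize(criterion, start, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise RuntimeError("REML optimization failed to find a finite criterion")
        th_s, th_u = np.exp(best.x)
        converged = bool(best.success)
    else:
        th_s = 1.0 / lambda_smooth

        def crit_u(log_tu):
            return criterion([np.log(th_s), log_tu[0]])

        res = optimize.minimize(crit_u, [0.0], method="Nelder-Mead",
                                options={"xatol": 1e-4, "maxiter": 200})
        th_u = float(np.exp(res.x[0]))
        converged = bool(res.success)

    # joint penalized solve for coefficients and posterior covariance
    C = np.column_stack([X, Zs, Zu])
    pen = np.concatenate([np.zeros(p), np.full(ks, 1.0 / max(th_s, 1e-12)),
                          np.full(G, 1.0 / max(th_u, 1e-12))])
    M = C.T @ C + np.diag(pen)
    Minv = np.linalg.inv(M)
    coef = Minv @ (C.T @ y)
    resid = y - C @ coef
    # REML-scale residual variance from the profiled criterion quantities
    V0 = np.eye(N) + th_s * (Zs @ Zs.T) + th_u * (Zu @ Zu.T)
    c, lowf = cho_factor(V0)
    Vi_X = cho_solve((c, lowf), X)
    A = X.T @ Vi_X
    beta_gls = np.linalg.solve(A, X.T @ cho_solve((c, lowf), y))
    r = y - X @ beta_gls
    sigma2 = float(r @ cho_solve((c, lowf), r)) / (N - p)

    fit = TrajectoryFit(
        basis=basis,
        coef=coef,
        cov_unscaled=Minv,
        sigma2=sigma2,
        sigma2_smooth=th_s * sigma2,
        sigma2_subject=th_u * sigma2,
        lam=1.0 / th_s if th_s > 0 else np.inf,
        subjects=labels,
        age_range=(float(ages.min()), float(ages.max())),
        grid=np.empty(0),
        fitted=np.empty(0),
        ci_lower=np.empty(0),
        ci_upper=np.empty(0),
        derivative=np.empty(0),
        converged=converged,
    )
    if grid is None:
        lo, hi = fit.age_range
        grid = np.arange(lo, hi + 1e-9, GRID_STEP)  # never past the data range
    fitted, lo_ci, hi_ci = predict_with_ci(fit, grid, level=ci_level)
    fit.grid = np.asarray(grid, dtype=float)
    fit.fitted = fitted
    fit.ci_lower = lo_ci
    fit.ci_upper = hi_ci
    fit.derivative = rate_of_change(fit, grid)
    return fit


def _population_rows(fit: TrajectoryFit, grid: np.ndarray, deriv: int = 0) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    Xg = fit.basis.fixed(grid, deriv)
    Zg = fit.basis.wiggly(grid, deriv)
    G = fit.subjects.size
    return np.column_stack([Xg, Zg, np.zeros((grid.size, G))])


def predict_with_ci(
    fit: TrajectoryFit, grid: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population mean curve with a pointwise confidence band.

    The band is the empirical-Bayes posterior band fitted +/- z * SE from
    the joint coefficient posterior covariance (random intercepts set to
    zero, i.e., the population curve).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.age_range
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        warnings.warn("grid extends beyond the fitted age range (extrapolation)", stacklevel=2)
    rows = _population_rows(fit, grid)
    fitted = rows @ fit.coef
    var = fit.sigma2 * np.einsum("ij,jk,ik->i", rows, fit.cov_unscaled, rows)
    from scipy.stats import norm

    zq = norm.ppf(0.5 + level / 2)
    se = np.sqrt(np.maximum(var, 0.0))
    return fitted, fitted - zq * se, fitted + zq * se


def rate_of_change(fit: TrajectoryFit, grid: np.ndarray | None = None) -> np.ndarray:
    """Analytic first derivative of the fitted population curve."""
    if grid is None:
        grid = fit.grid
    rows = _population_rows(fit, grid, deriv=1)
    return rows @ fit.coef


def peak_change_age(derivative: np.ndarray, grid: np.ndarray) -> float:
    """Grid age maximizing |derivative|; ties -> smallest age; NaN if flat."""
    derivative = np.asarray(derivative, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if derivative.size != grid.size:
        raise ValueError("derivative and grid lengths differ")
    mag = np.abs(derivative)
    if not np.any(mag > 0):
        return float("nan")
    return float(grid[int(np.argmax(mag))])


def fit_summary_table(fit: TrajectoryFit):
    """Grid curves as a DataFrame (age, fitted, lo, hi, derivative)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "age": fit.grid,
            "fitted": fit.fitted,
            "lo": fit.ci_lower,
            "hi": fit.ci_upper,
            "derivative": fit.derivative,
        }
    )
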