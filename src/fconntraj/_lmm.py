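"""Vectorized REML estimation for random-intercept linear mixed models.

The model, fitted independently for each of E response columns but sharing
one design matrix ``X`` (N x p) and one subject grouping, is

    y = X b + u_subject + eps,    u ~ N(0, sigma_u^2),  eps ~ N(0, sigma^2).

Writing theta = sigma_u^2 / sigma^2, the marginal covariance is
sigma^2 * V0 with V0 = I + theta * Z Z' block-diagonal over subjects, so
V0^{-1} has the Woodbury form I - theta/(1 + theta*n_i) * J_i per subject.
Every REML quantity (GLS coefficients, residual quadratic form, log|V0|,
log|X'V0^{-1}X|) reduces to per-subject sums of X and y, which makes the
profiled REML criterion evaluable for *all* response columns at once for
any per-column theta vector.  Optimization is a coarse log-grid scan
followed by vectorized golden-section refinement, which is exact for this
single-ratio model class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class RandomInterceptFit:
    """Result of a vectorized random-intercept REML fit.

    Attributes
    ----------
    beta : (p, E) fixed-effect estimates per response column.
    cov_beta : (E, p, p) covariance of the estimates.
    theta : (E,) variance ratio sigma_u^2 / sigma^2.
    sigma2 : (E,) residual variance.
    sigma2_u : (E,) subject random-intercept variance.
    blups : (G, E) empirical-Bayes subject intercepts, rows ordered
        by ``group_labels``.
    group_labels : (G,) the distinct group identifiers.
    singular : (E,) True where the residual quadratic form collapsed
        (perfect fit); estimates for those columns are unreliable.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    theta: np.ndarray
    sigma2: np.ndarray
    sigma2_u: np.ndarray
    blups: np.ndarray
    group_labels: np.ndarray
    singular: np.ndarray

    def se(self, j: int) -> np.ndarray:
        """Standard error of coefficient ``j`` for every column."""
        return np.sqrt(self.cov_beta[:, j, j])


class _Sufficients:
    """Per-group sufficient statistics shared across criterion evaluations."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.N, self.p = X.shape
        self.E = Y.shape[1]
        self.labels, inv = np.unique(groups, return_inverse=True)
        self.G = self.labels.size
        self.n_i = np.bincount(inv, minlength=self.G).astype(float)
        # group sums: s_i (G,p) of X rows, t_i (G,E) of y values
        self.Sx = np.zeros((self.G, self.p))
        np.add.at(self.Sx, inv, X)
        self.Ty = np.zeros((self.G, self.E))
        np.add.at(self.Ty, inv, Y)
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.yty = np.einsum("ne,ne->e", Y, Y)
        self.inv = inv

    def criterion(self, theta: np.ndarray):
        """-2 REML log-likelihood (up to a constant) for per-column theta.

        theta may be scalar or (E,).  Returns (crit, beta, A, quad) where
        A is (E,p,p) = X'V0^{-1}X and quad is the residual quadratic form.
        """
        theta = np.broadcast_to(np.asarray(theta, dtype=float), (self.E,))
        # w_{ie} = theta_e / (1 + theta_e * n_i)
        w = theta[None, :] / (1.0 + theta[None, :] * self.n_i[:, None])  # (G,E)
        A = self.XtX[None, :, :] - np.einsum("ge,gp,gq->epq", w, self.Sx, self.Sx)
        c = self.XtY - np.einsum("ge,gp->pe", w * self.Ty, self.Sx)
        d = self.yty - np.einsum("ge,ge->e", w, self.Ty**2)
        beta = np.linalg.solve(A, c.T[:, :, None])[:, :, 0]  # (E,p)
        quad = d - np.einsum("ep,pe->e", beta, c)
        quad = np.maximum(quad, 0.0)
        sign, logdetA = np.linalg.slogdet(A)
        logdetV = np.log1p(np.outer(self.n_i, theta)).sum(axis=0)  # (E,)
        df = self.N - self.p
        with np.errstate(divide="ignore"):
            crit = logdetV + logdetA + df * np.log(quad)
        crit = np.where(quad <= 0, np.inf, crit)
        return crit, beta.T, A, quad


def fit_random_intercept(
    Y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    *,
    grid: np.ndarray | None = None,
    refine_iters: int = 40,
) -> RandomInterceptFit:
    """REML-fit ``y = X b + u_group + eps`` for every column of ``Y``.

    Parameters
    ----------
    Y : (N, E) response matrix (E columns fitted independently).
    X : (N, p) shared fixed-effect design; must have full column rank.
    groups : (N,) group (subject) identifiers.
    grid : optional 1-D array of candidate variance ratios for the coarse
        scan; defaults to {0} plus a log-spaced grid 1e-6..1e4.
    refine_iters : golden-section iterations after the grid scan.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != np.asarray(X).shape[0]:
        Y = Y.T
    X = np.asarray(X, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X disagree on the number of observations")
    groups = np.asarray(groups)
    if groups.shape[0] != X.shape[0]:
        raise ValueError("groups length must match number of observations")
    N, p = X.shape
    if N <= p:
        raise ValueError("need more observations than fixed-effect columns")

    suff = _Sufficients(Y, X, groups)
    if grid is None:
        grid = np.concatenate(([0.0], np.logspace(-6, 4, 51)))
    crits = np.empty((grid.size, suff.E))
    for k, th in enumerate(grid):
        crits[k], _, _, _ = suff.criterion(th)
    best = np.argmin(crits, axis=0)

    # golden-section refinement within the bracketing grid cells
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]
    a, b = lo.copy(), hi.copy()
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, _, _, _ = suff.criterion(x1)
    f2, _, _, _ = suff.criterion(x2)
    for _ in range(refine_iters):
        use1 = f1 < f2  # shrink from the right
        b = np.where(use1, x2, b)
        a = np.where(use1, a, x1)
        x2_keep = np.where(use1, x1, a + _GOLDEN * (b - a))
        x1_keep = np.where(use1, b - _GOLDEN * (b - a), x2)
        f2_keep = np.where(use1, f1, np.nan)  # nan slots re-evaluated below
        f1_keep = np.where(use1, np.nan, f2)
        x1, x2 = x1_keep, x2_keep
        new_x = np.where(use1, x1, x2)
        f_new, _, _, _ = suff.criterion(new_x)
        f1 = np.where(use1, f_new, f1_keep)
        f2 = np.where(use1, f2_keep, f_new)
    theta = (a + b) / 2.0

    crit, beta, A, quad = suff.criterion(theta)
    df = N - p
    sigma2 = quad / df
    singular = quad <= max(N, suff.E) * 1e-12 * np.maximum(suff.yty, 1.0)
    cov_beta = np.linalg.inv(A) * sigma2[:, None, None]
    sigma2_u = theta * sigma2
    # BLUPs: u_i = theta/(1+theta n_i) * (t_i - s_i' beta)
    w = theta[None, :] / (1.0 + theta[None, :] * suff.n_i[:, None])
    resid_sums = suff.Ty - suff.Sx @ beta  # (G,E)
    blups = w * resid_sums
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        theta=theta,
        sigma2=sigma2,
        sigma2_u=sigma2_u,
        blups=blups,
        group_labels=suff.labels,
        singular=singular,
    )
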