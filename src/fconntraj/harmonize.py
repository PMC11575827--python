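"""Longitudinal ComBat harmonization of edge values.

Removes additive and multiplicative acquisition-sequence (batch) effects
from sessions x edges matrices while preserving age effects and subject
random intercepts.  Per edge the model is

    y = beta0 + beta1*age + gamma_batch + u_subject + eps,
    Var(eps) = delta2_batch * sigma^2,

fitted by REML on the homoscedastic random-intercept model with batch
fixed effects; batch location/scale parameters are then estimated from
standardized residuals and, with empirical Bayes on (default), shrunk
across edges toward a normal prior (additive) and an inverse-gamma prior
(multiplicative) with method-of-moments hyperparameters, via the classic
iterative conditional-posterior solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import fit_random_intercept


@dataclass
class HarmonizationModel:
    """Fitted longitudinal ComBat model for one edge table."""

    batches: list
    batch_sizes: np.ndarray  # (B,)
    beta: np.ndarray  # (p_nb, E) non-batch fixed effects (intercept, age...)
    sigma: np.ndarray  # (E,) residual SD of the mixed model
    sigma2_u: np.ndarray  # (E,) subject random-intercept variance
    gamma_hat: np.ndarray  # (B, E) additive batch effects, standardized units
    delta2_hat: np.ndarray  # (B, E) multiplicative batch effects (variance scale)
    gamma_star: np.ndarray  # (B, E) EB-shrunk (equal to *_hat when eb off)
    delta2_star: np.ndarray  # (B, E)
    eb: bool
    subjects: np.ndarray  # design rows the model was fitted on
    session_batch: np.ndarray
    ages: np.ndarray
    blups: np.ndarray  # (G, E)
    blup_subjects: np.ndarray
    identity: bool = False  # single-batch fit: apply is a no-op
    hyper: dict = field(default_factory=dict)

    def gamma_z_units(self) -> np.ndarray:
        """Additive batch effects on the Fisher-z scale, (B, E)."""
        return self.gamma_hat * self.sigma[None, :]

    def to_json(self) -> str:
        payload = {
            "batches": [str(b) for b in self.batches],
            "eb": self.eb,
            "identity": self.identity,
            "batch_sizes": self.batch_sizes.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "hyper": {k: np.asarray(v).tolist() for k, v in self.hyper.items()},
        }
        return json.dumps(payload, indent=2)


def _design(design: pd.DataFrame, batches: list, age_basis: str) -> tuple[np.ndarray, np.ndarray]:
    """Non-batch design X_nb and batch dummy block (reference = batches[0])."""
    ages = design["age_weeks"].to_numpy(dtype=float)
    if age_basis == "linear":
        X_nb = np.column_stack([np.ones_like(ages), ages])
    elif age_basis == "spline":
        from .trajectory import bspline_basis

        B, _ = bspline_basis(ages, ages, df=5)
        X_nb = np.column_stack([np.ones_like(ages), B[:, 1:]])
    else:
        raise ValueError("age_basis must be 'linear' or 'spline'")
    dummies = np.column_stack(
        [(design["sequence_id"] == b).to_numpy(dtype=float) for b in batches[1:]]
    ) if len(batches) > 1 else np.zeros((len(design), 0))
    return X_nb, dummies


def fit_longcombat(
    edges: np.ndarray,
    design: pd.DataFrame,
    batch_col: str = "sequence_id",
    eb: bool = True,
    age_basis: str = "linear",
) -> HarmonizationModel:
    """Fit the longitudinal ComBat model to a sessions x edges table.

    ``design`` must carry subject_id, age_weeks and the batch column.
    Every batch needs at least 2 sessions; a single-batch table yields an
    identity model with a warning.
    """
    edges = np.asarray(edges, dtype=float)
    design = design.reset_index(drop=True)
    if batch_col != "sequence_id":
        design = design.rename(columns={batch_col: "sequence_id"})
    batch_series = design["sequence_id"]
    batches = sorted(batch_series.unique().tolist())
    sizes = np.array([(batch_series == b).sum() for b in batches])
    E = edges.shape[1]

    if len(batches) < 2:
        warnings.warn("single batch: harmonization is an identity transform", stacklevel=2)
        fit = fit_random_intercept(edges, _design(design, batches, age_basis)[0], design["subject_id"].to_numpy())
        return HarmonizationModel(
            batches=batches,
            batch_sizes=sizes,
            beta=fit.beta,
            sigma=np.sqrt(fit.sigma2),
            sigma2_u=fit.sigma2_u,
            gamma_hat=np.zeros((1, E)),
            delta2_hat=np.ones((1, E)),
            gamma_star=np.zeros((1, E)),
            delta2_star=np.ones((1, E)),
            eb=eb,
            subjects=design["subject_id"].to_numpy(),
            session_batch=batch_series.to_numpy(),
            ages=design["age_weeks"].to_numpy(dtype=float),
            blups=fit.blups,
            blup_subjects=fit.group_labels,
            identity=True,
        )
    if (sizes < 2).any():
        small = [b for b, n in zip(batches, sizes) if n < 2]
        raise ValueError(f"batches with fewer than 2 sessions: {small}")

    X_nb, dummies = _design(design, batches, age_basis)
    X = np.column_stack([X_nb, dummies])
    subjects = design["subject_id"].to_numpy()
    fit = fit_random_intercept(edges, X, subjects)

    p_nb = X_nb.shape[1]
    beta_nb = fit.beta[:p_nb].copy()
    gamma_ref = np.vstack([np.zeros((1, E)), fit.beta[p_nb:]])  # (B,E), ref coded
    # identifiability: weighted (by batch size) mean of gamma absorbed into intercept
    wmean = (sizes[:, None] * gamma_ref).sum(axis=0) / sizes.sum()
    gamma_centered = gamma_ref - wmean[None, :]
    beta_nb[0] += wmean

    sigma = np.sqrt(fit.sigma2)
    sigma = np.where(sigma > 0, sigma, 1.0)
    # subject BLUP per session row
    pos = {s: k for k, s in enumerate(fit.group_labels)}
    row_u = fit.blups[[pos[s] for s in subjects]]
    fit_nb = X_nb @ beta_nb + row_u
    z = (edges - fit_nb) / sigma[None, :]  # contains gamma_b/sigma + scaled noise

    b_idx = np.array([batches.index(b) for b in batch_series])
    gamma_hat = np.vstack([z[b_idx == k].mean(axis=0) for k in range(len(batches))])
    # Multiplicative effects from *marginal* batch variances: the marginal
    # residual y - X beta contains u + delta_b*sigma*eps, so subtracting the
    # REML subject variance isolates delta2_b * sigma2 even when most
    # subjects contribute a single session (where BLUP-based conditional
    # residuals would dilute the batch scale toward the pooled value).
    marg = edges - X_nb @ beta_nb
    v_b = np.vstack([marg[b_idx == k].var(axis=0, ddof=1) for k in range(len(batches))])
    delta2_hat = (v_b - fit.sigma2_u[None, :]) / fit.sigma2[None, :]
    delta2_hat = np.maximum(delta2_hat, 1e-3)

    hyper: dict = {}
    if eb and E >= 2:
        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        m = delta2_hat.mean(axis=1)
        s2 = delta2_hat.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = (2 * s2 + m**2) / s2
            theta = (m * s2 + m**3) / s2
        hyper = {"gamma_bar": gamma_bar, "tau2": tau2, "lambda": lam, "theta": theta}
        for k in range(len(batches)):
            if not np.isfinite(lam[k]) or tau2[k] <= 0:
                gamma_star[k] = gamma_hat[k]
                delta2_star[k] = delta2_hat[k]
                continue
            g, d2 = _it_sol(
                z[b_idx == k],
                gamma_hat[k],
                delta2_hat[k],
                gamma_bar[k],
                tau2[k],
                lam[k],
                theta[k],
            )
            gamma_star[k] = g
            delta2_star[k] = d2
    else:
        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()

    return HarmonizationModel(
        batches=batches,
        batch_sizes=sizes,
        beta=beta_nb,
        sigma=sigma,
        sigma2_u=fit.sigma2_u,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        eb=eb,
        subjects=subjects,
        session_batch=batch_series.to_numpy(),
        ages=design["age_weeks"].to_numpy(dtype=float),
        blups=fit.blups,
        blup_subjects=fit.group_labels,
        hyper=hyper,
    )


def _it_sol(z_b, gamma_hat, delta2_hat, gamma_bar, tau2, lam, theta, tol=1e-6, max_iter=100):
    """Iterative conditional posterior for one batch's EB estimates."""
    n_b = z_b.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
        ssq = ((z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * ssq) / (n_b / 2 + lam - 1)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def apply_longcombat(
    model: HarmonizationModel, edges: np.ndarray, design: pd.DataFrame
) -> np.ndarray:
    """Remove the fitted batch effects; age effects and intercepts restored.

    y_adj = sigma * (z - gamma*_b) / sqrt(delta2*_b) + fitted_non_batch.
    The design must be the one the model was fitted on (row-linked BLUPs);
    an unseen batch label raises.
    """
    edges = np.asarray(edges, dtype=float)
    design = design.reset_index(drop=True)
    unseen = set(design["sequence_id"]) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch labels: {sorted(unseen)}")
    if model.identity:
        return edges.copy()
    if len(design) != len(model.subjects) or not (
        np.array_equal(design["subject_id"].to_numpy(), model.subjects)
        and np.allclose(design["age_weeks"].to_numpy(dtype=float), model.ages)
    ):
        raise ValueError("design does not match the design the model was fitted on")

    ages = model.ages
    X_nb = np.column_stack([np.ones_like(ages), ages]) if model.beta.shape[0] == 2 else None
    if X_nb is None:
        raise ValueError("stored model uses a non-linear age basis; re-fit to apply")
    pos = {s: k for k, s in enumerate(model.blup_subjects)}
    row_u = model.blups[[pos[s] for s in model.subjects]]
    fit_nb = X_nb @ model.beta + row_u
    z = (edges - fit_nb) / model.sigma[None, :]
    b_idx = np.array([model.batches.index(b) for b in design["sequence_id"]])
    z_adj = (z - model.gamma_star[b_idx]) / np.sqrt(model.delta2_star[b_idx])
    return model.sigma[None, :] * z_adj + fit_nb


def batch_ftest(edges: np.ndarray, design: pd.DataFrame) -> np.ndarray:
    """Per-edge one-way F-test p-value for residual batch differences.

    Residuals are taken from the age + subject-intercept mixed model
    (no batch terms); under successful harmonization the batch F-test is
    non-significant in expectation.
    """
    edges = np.asarray(edges, dtype=float)
    design = design.reset_index(drop=True)
    ages = design["age_weeks"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(ages), ages])
    fit = fit_random_intercept(edges, X, design["subject_id"].to_numpy())
    pos = {s: k for k, s in enumerate(fit.group_labels)}
    row_u = fit.blups[[pos[s] for s in design["subject_id"]]]
    resid = edges - X @ fit.beta - row_u
    groups = design["sequence_id"].to_numpy()
    labels = pd.unique(groups)
    pvals = np.empty(edges.shape[1])
    for e in range(edges.shape[1]):
        samples = [resid[groups == g, e] for g in labels]
        pvals[e] = stats.f_oneway(*samples).pvalue if len(labels) > 1 else 1.0
    return pvals


def harmonization_report(
    before: np.ndarray, after: np.ndarray, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-batch residual location/scale before vs after harmonization.

    Residuals are relative to the age + subject mixed-model fit, averaged
    across edges; one row per batch with before/after means and variances.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after shape mismatch")
    design = design.reset_index(drop=True)

    def _batch_stats(mat):
        ages = design["age_weeks"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(ages), ages])
        fit = fit_random_intercept(mat, X, design["subject_id"].to_numpy())
        pos = {s: k for k, s in enumerate(fit.group_labels)}
        row_u = fit.blups[[pos[s] for s in design["subject_id"]]]
        resid = mat - X @ fit.beta - row_u
        out = {}
        for b in sorted(design["sequence_id"].unique()):
            r = resid[(design["sequence_id"] == b).to_numpy()]
            out[b] = (float(r.mean()), float(r.var(ddof=1)))
        return out

    sb, sa = _batch_stats(before), _batch_stats(after)
    rows = []
    for b in sb:
        rows.append(
            {
                "batch": b,
                "mean_before": sb[b][0],
                "mean_after": sa[b][0],
                "var_before": sb[b][1],
                "var_after": sa[b][1],
            }
        )
    return pd.DataFrame(rows)
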