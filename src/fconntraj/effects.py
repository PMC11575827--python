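"""Edge-wise age-effect inference and its diagnostics.

Each edge's Fisher-z values are regressed on age in a random-intercept
mixed model (one intercept per subject, REML), the age slope is tested
with a Wald statistic, and Benjamini-Hochberg FDR is applied across
edges.  Significant edges are classified by slope sign and averaged into
global and network-pair growth series; Euclidean-distance and QC-FC
diagnostics check that results are not motion- or distance-driven.
"""

from __future__ import annotations

import warnings
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._lmm import fit_random_intercept
from .connectome import Atlas, edge_index


def edgewise_age_model(
    edges: np.ndarray,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    subset: str | None = None,
    df_method: str = "subjects",
) -> pd.DataFrame:
    """Per-edge random-intercept age regression with BH-FDR.

    Returns a table (edge_id, beta, se, p, q, sign) where sign is
    positive/negative for FDR-significant edges and null otherwise.
    ``subset`` restricts the fit to the fetal or infant cohort (the
    follow-up within-period analyses).

    The Wald statistic beta/SE is referred to a t distribution with
    n_subjects - 2 degrees of freedom by default (``df_method='subjects'``),
    the conservative repeated-measures reference for a covariate that
    varies mostly between subjects; ``df_method='normal'`` uses the
    large-sample normal reference instead.
    """
    edges = np.asarray(edges, dtype=float)
    cohort = cohort.reset_index(drop=True)
    if subset is not None:
        keep = (cohort["cohort"] == subset).to_numpy()
        edges = edges[keep]
        cohort = cohort[keep].reset_index(drop=True)
    if cohort["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    ages = cohort["age_weeks"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(ages), ages])
    fit = fit_random_intercept(edges, X, cohort["subject_id"].to_numpy())
    beta = fit.beta[1]
    se = fit.se(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    if df_method == "subjects":
        df = max(cohort["subject_id"].nunique() - 2, 1)
        p = 2 * stats.t.sf(np.abs(zstat), df)
    elif df_method == "normal":
        p = 2 * stats.norm.sf(np.abs(zstat))
    else:
        raise ValueError("df_method must be 'subjects' or 'normal'")
    p = np.where(fit.singular, np.nan, p)
    if fit.singular.any():
        warnings.warn(
            f"{int(fit.singular.sum())} singular edge fits excluded from FDR", stacklevel=2
        )
    reject, q = fdr_bh(p, alpha)
    sign = np.where(reject & (beta > 0), "positive", np.where(reject & (beta < 0), "negative", "null"))
    return pd.DataFrame(
        {
            "edge_id": np.arange(edges.shape[1]),
            "beta": beta,
            "se": se,
            "p": p,
            "q": q,
            "sign": sign,
            "singular": fit.singular,
        }
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, q-values).

    NaN p-values are excluded from the procedure (never rejected, q=NaN)
    with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if np.nanmin(p, initial=0) < 0 or np.nanmax(p, initial=0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} NaN p-values excluded from FDR", stacklevel=2)
    reject = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        reject[ok] = rej
        qvals[ok] = qv
    return reject, qvals


def average_significant(
    edges: np.ndarray, effects: pd.DataFrame, sign: str
) -> np.ndarray:
    """Per-session mean z over edges with the stated significant sign.

    Returns a length-n_sessions series; all-NaN with a warning when the
    significant set is empty.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    edges = np.asarray(edges, dtype=float)
    idx = effects.loc[effects["sign"] == sign, "edge_id"].to_numpy()
    if idx.size == 0:
        warnings.warn(f"no {sign} significant edges; series is NaN", stacklevel=2)
        return np.full(edges.shape[0], np.nan)
    return edges[:, idx].mean(axis=1)


def network_pairs(atlas: Atlas) -> list[tuple]:
    """All unordered network pairs including within-network pairs.

    K networks yield K(K+1)/2 pairs (8 networks -> 36)."""
    return list(combinations_with_replacement(atlas.networks, 2))


def network_pair_series(
    edges: np.ndarray, effects: pd.DataFrame, atlas: Atlas
) -> pd.DataFrame:
    """Average significant edges (either sign) within each network pair.

    Long table (pair, network_a, network_b, session, value, n_edges);
    pairs with no significant edges appear with NaN values and
    n_edges = 0.
    """
    edges = np.asarray(edges, dtype=float)
    P = atlas.n_parcels
    ii, jj = edge_index(P)
    if edges.shape[1] != ii.size:
        raise ValueError("edge table width does not match atlas parcel count")
    lab = atlas.labels
    pair_of_edge = [tuple(sorted((lab[a], lab[b]))) for a, b in zip(ii, jj)]
    sig = effects["sign"].to_numpy() != "null"
    rows = []
    n_sessions = edges.shape[0]
    for pair in network_pairs(atlas):
        members = np.array([k for k, pe in enumerate(pair_of_edge) if pe == pair])
        sig_members = members[sig[members]] if members.size else members
        if sig_members.size:
            series = edges[:, sig_members].mean(axis=1)
        else:
            series = np.full(n_sessions, np.nan)
        for s in range(n_sessions):
            rows.append(
                {
                    "pair": f"{pair[0]}-{pair[1]}",
                    "network_a": pair[0],
                    "network_b": pair[1],
                    "session": s,
                    "value": series[s],
                    "n_edges": int(sig_members.size),
                }
            )
    return pd.DataFrame(rows)


def edge_distance(coords: np.ndarray, n_parcels: int | None = None) -> np.ndarray:
    """Euclidean distance between parcel-centre coordinates per edge."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_parcels, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("missing coordinates")
    if n_parcels is not None and coords.shape[0] != n_parcels:
        raise ValueError("coordinate count does not match parcel count")
    ii, jj = edge_index(coords.shape[0])
    return np.linalg.norm(coords[ii] - coords[jj], axis=1)


def compare_distance_distributions(
    effects: pd.DataFrame, distances: np.ndarray
) -> dict:
    """Rank-based location test of positive-set vs negative-set distances."""
    distances = np.asarray(distances, dtype=float)
    pos = distances[effects["sign"].to_numpy() == "positive"]
    neg = distances[effects["sign"].to_numpy() == "negative"]
    if pos.size == 0 or neg.size == 0:
        return {"statistic": np.nan, "p": np.nan, "n_pos": int(pos.size), "n_neg": int(neg.size)}
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_pos": int(pos.size),
        "n_neg": int(neg.size),
        "median_pos": float(np.median(pos)),
        "median_neg": float(np.median(neg)),
    }


def qcfc_distance(
    edges: np.ndarray, session_mean_fd: np.ndarray, distances: np.ndarray
) -> float:
    """QC-FC distance dependence: one scalar correlation.

    Per edge, correlate its z values with per-session mean FD across
    sessions; then correlate those edge-wise motion correlations with
    edge Euclidean distances.  Values near 0 indicate results are not
    driven by a distance-dependent motion artifact.
    """
    edges = np.asarray(edges, dtype=float)
    fd = np.asarray(session_mean_fd, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if edges.shape[0] != fd.size:
        raise ValueError("one mean-FD value per session required")
    if edges.shape[0] < 3:
        raise ValueError("need at least 3 sessions for QC-FC correlation")
    if fd.std() == 0:
        raise ValueError("constant motion: QC-FC correlation undefined")
    fd_c = fd - fd.mean()
    ec = edges - edges.mean(axis=0)
    denom = np.sqrt((ec**2).sum(axis=0)) * np.sqrt((fd_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        qcfc = (ec * fd_c[:, None]).sum(axis=0) / denom
    ok = np.isfinite(qcfc) & np.isfinite(distances)
    if ok.sum() < 3:
        raise ValueError("too few edges with defined QC-FC values")
    return float(np.corrcoef(qcfc[ok], distances[ok])[0, 1])
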