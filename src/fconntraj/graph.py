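"""Proportional thresholding and node-wise graph efficiency.

The RSFC matrix is binarized by retaining the top proportion (default
15%) of signed Fisher-z values over the unique off-diagonal pairs; hop
distances on the resulting unweighted graph give per-node global
efficiency (mean inverse shortest-path distance to all other nodes,
1/inf = 0 for unreachable pairs) and local efficiency (global efficiency
of the subgraph induced by a node's neighbors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import edge_index, n_edges as edge_count


def threshold_top_proportion(z_matrix: np.ndarray, proportion: float = 0.15) -> np.ndarray:
    """Binary adjacency retaining the strongest ``proportion`` of edges.

    Keeps the ceil(proportion * P(P-1)/2) largest signed values of the
    strict upper triangle; ties at the cut are broken by canonical edge
    order.  Output is symmetric 0/1 with a zero diagonal.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    m = np.asarray(z_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    P = m.shape[0]
    ii, jj = edge_index(P)
    vals = m[ii, jj]
    k = int(np.ceil(proportion * vals.size))
    # primary key: value descending; secondary: canonical edge order
    order = np.lexsort((np.arange(vals.size), -vals))
    keep = order[:k]
    adj = np.zeros((P, P), dtype=int)
    adj[ii[keep], jj[keep]] = 1
    adj[jj[keep], ii[keep]] = 1
    return adj


def shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """Hop-count distance matrix; unreachable pairs are +inf, d(n,n)=0."""
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if adj.shape[0] == 1:
        return np.zeros((1, 1))
    d = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    return d


def global_efficiency(dist: np.ndarray) -> np.ndarray:
    """Per-node global efficiency: mean over m != n of 1/d(n, m)."""
    dist = np.asarray(dist, dtype=float)
    P = dist.shape[0]
    if P < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (P - 1)


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per-node local efficiency: global efficiency of the neighbor subgraph.

    Nodes with degree < 2 score 0 (no pairs among neighbors).
    """
    adj = np.asarray(adj)
    P = adj.shape[0]
    out = np.zeros(P)
    for n in range(P):
        nbrs = np.flatnonzero(adj[n])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = shortest_path_lengths(sub)
        out[n] = global_efficiency(d).mean()
    return out


def node_efficiencies(z_matrix: np.ndarray, proportion: float = 0.15) -> pd.DataFrame:
    """Threshold one RSFC matrix and compute per-node GE and LE."""
    adj = threshold_top_proportion(z_matrix, proportion)
    d = shortest_path_lengths(adj)
    return pd.DataFrame(
        {
            "node": np.arange(adj.shape[0]),
            "ge": global_efficiency(d),
            "le": local_efficiency(adj),
            "degree": adj.sum(axis=1),
        }
    )


def session_efficiencies(
    edge_table: np.ndarray, n_parcels: int, proportion: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """GE and LE for every session of a sessions x edges table.

    Returns (ge, le), each (n_sessions, n_parcels)."""
    from .connectome import devectorize_edges

    edge_table = np.asarray(edge_table, dtype=float)
    if edge_table.shape[1] != edge_count(n_parcels):
        raise ValueError("edge table width does not match n_parcels")
    S = edge_table.shape[0]
    ge = np.empty((S, n_parcels))
    le = np.empty((S, n_parcels))
    for s in range(S):
        adj = threshold_top_proportion(devectorize_edges(edge_table[s], n_parcels), proportion)
        d = shortest_path_lengths(adj)
        ge[s] = global_efficiency(d)
        le[s] = local_efficiency(adj)
    return ge, le


def efficiency_trajectories(
    values: np.ndarray,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    basis_dim: int = 10,
    grid: np.ndarray | None = None,
):
    """Node-wise age effects plus spline growth fits of mean series.

    ``values`` is (n_sessions, n_nodes) of GE or LE.  Age effects reuse
    the edge-wise mixed model with BH-FDR over nodes; growth curves are
    fitted to the average over significantly increasing / decreasing
    nodes, mirroring the edge-level analysis.
    """
    from .effects import average_significant, edgewise_age_model
    from .trajectory import fit_gamm

    values = np.asarray(values, dtype=float)
    effects = edgewise_age_model(values, cohort, alpha=alpha).rename(
        columns={"edge_id": "node"}
    )
    fits = {}
    for sign in ("positive", "negative"):
        eff = effects.rename(columns={"node": "edge_id"})
        if (eff["sign"] == sign).any():
            series = average_significant(values, eff, sign)
            fits[sign] = fit_gamm(
                series,
                cohort["age_weeks"].to_numpy(dtype=float),
                cohort["subject_id"].to_numpy(),
                basis_dim=basis_dim,
                grid=grid,
            )
        else:
            fits[sign] = None
    return effects, fits
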