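"""RSFC matrix construction: parcel averaging, Pearson correlation on
retained frames, Fisher-z transform, canonical edge vectorization, atlas
handling, and the group-mean one-sample t test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ATANH_EPS = 1e-7

#: Network labels of the full 8-network study atlas.
STUDY_NETWORKS = ("RS", "LS", "LT", "Occ", "Sub", "Inf", "Sup", "RT")


@dataclass
class Atlas:
    """Parcel-to-network assignment.

    labels[i] is the network of parcel i; every parcel belongs to exactly
    one network.
    """

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("atlas labels must be one label per parcel")

    @property
    def n_parcels(self) -> int:
        return self.labels.size

    @property
    def networks(self) -> list:
        return sorted(pd.unique(self.labels).tolist())

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @classmethod
    def synthetic(cls, n_parcels: int, n_networks: int) -> "Atlas":
        """Even block assignment of parcels to networks (synthetic atlas)."""
        if n_networks > n_parcels:
            raise ValueError("more networks than parcels")
        names = (
            list(STUDY_NETWORKS)
            if n_networks == len(STUDY_NETWORKS)
            else [f"net_{k}" for k in range(n_networks)]
        )
        labels = [names[(i * n_networks) // n_parcels] for i in range(n_parcels)]
        return cls(labels=np.array(labels))

    @classmethod
    def from_csv(cls, path) -> "Atlas":
        df = pd.read_csv(path)
        df = df.sort_values(df.columns[0])
        return cls(labels=df[df.columns[1]].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"parcel_id": np.arange(self.n_parcels), "network": self.labels}
        ).to_csv(path, index=False)


def parcel_means(voxel_ts: np.ndarray, parcel_labels: np.ndarray) -> np.ndarray:
    """Average voxel time series within parcels -> (n_frames, n_parcels).

    Parcels are the sorted unique labels; an empty parcel (a label with no
    voxels) cannot occur by construction, but a label list that skips an
    integer parcel id raises with the parcel named.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    parcel_labels = np.asarray(parcel_labels)
    if voxel_ts.ndim != 2 or voxel_ts.shape[1] != parcel_labels.size:
        raise ValueError("voxel_ts must be (n_frames, n_voxels) matching labels")
    uniq = np.unique(parcel_labels)
    if np.issubdtype(uniq.dtype, np.integer):
        missing = set(range(int(uniq.min()), int(uniq.max()) + 1)) - set(uniq.tolist())
        if missing:
            raise ValueError(f"empty parcels: {sorted(missing)}")
    out = np.empty((voxel_ts.shape[0], uniq.size))
    for k, lbl in enumerate(uniq):
        out[:, k] = voxel_ts[:, parcel_labels == lbl].mean(axis=1)
    return out


def correlation_matrix(ts: np.ndarray, keep_flags: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between parcels, on retained frames only."""
    ts = np.asarray(ts, dtype=float)
    if keep_flags is not None:
        ts = ts[np.asarray(keep_flags, dtype=bool)]
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 retained frames for correlation")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance parcels: {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r_matrix: np.ndarray, eps: float = ATANH_EPS) -> np.ndarray:
    """Fisher z transform atanh(r), with |r| clipped to 1 - eps.

    The diagonal is stored as 0 and excluded from downstream statistics.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.nanmax(np.abs(r)) > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def edge_index(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: strict upper triangle, row-major."""
    return np.triu_indices(n_parcels, k=1)


def n_edges(n_parcels: int) -> int:
    return n_parcels * (n_parcels - 1) // 2


def vectorize_edges(matrix: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Strict-upper-triangle edge vector of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, rtol=rtol, atol=1e-10):
        raise ValueError("matrix is not symmetric within tolerance")
    i, j = edge_index(m.shape[0])
    return m[i, j]


def devectorize_edges(vec: np.ndarray, n_parcels: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; diagonal filled with ``diag``."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_edges(n_parcels):
        raise ValueError("edge vector length does not match n_parcels")
    m = np.full((n_parcels, n_parcels), diag)
    i, j = edge_index(n_parcels)
    m[i, j] = vec
    m[j, i] = vec
    return m


def group_mean_ttest(z_stack: np.ndarray) -> pd.DataFrame:
    """One-sample t test of Fisher-z values against 0 for every edge.

    ``z_stack`` is (n_sessions, n_edges); returns a table of t, two-sided
    p and a degenerate flag for zero-variance edges.
    """
    z = np.asarray(z_stack, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need at least 2 sessions")
    n = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {"edge_id": np.arange(z.shape[1]), "mean_z": mean, "t": t, "p": p, "degenerate": degenerate}
    )


def build_connectome(
    ts: np.ndarray, keep_flags: np.ndarray | None = None
) -> np.ndarray:
    """Censored-frame Pearson correlation followed by Fisher z."""
    return fisher_z(correlation_matrix(ts, keep_flags))


def write_matrix_tsv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, matrix, delimiter="\t")


def read_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")
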