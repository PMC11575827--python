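"""Synthetic perinatal cohorts, edge trajectories and scan fixtures.

Emulates the structure of a longitudinal fetal/infant resting-state fMRI
study spanning roughly 25-55 post-conceptual weeks: ~140 subjects scanned
1-4 times across the birth transition, five acquisition sequences acting
as batches, and parcel-level connectivity whose edge-wise mean follows one
of four trajectory families (sigmoid surge around birth, linear increase,
linear decrease, flat).  Every generator is seeded and returns its ground
truth so downstream stages are testable without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Session-count distribution and scan counts as observed in the study
# cohort: 108 subjects with one session, 21 with two, 10 with three, one
# with four (184 usable sessions from 140 subjects).
STUDY_SESSION_WEIGHTS: dict[int, float] = {
    1: 108 / 140,
    2: 21 / 140,
    3: 10 / 140,
    4: 1 / 140,
}

#: Acquisition sequences and their scan counts (fetal: 75+51, infant: 11+7+40).
STUDY_SEQUENCES: dict[str, dict[str, float]] = {
    "fetal": {"fetal_i": 75, "fetal_ii": 51},
    "infant": {"infant_i": 11, "infant_ii": 7, "infant_iii": 40},
}

AGE_REF_WEEKS = 25.0  # start of the study window; reference age for linear truths


class ConfigurationError(ValueError):
    """Invalid simulation / pipeline configuration."""


@dataclass
class CohortSpec:
    """Design of a synthetic longitudinal cohort.

    Defaults mirror the study conditions: 140 subjects, the observed
    session-count distribution, fetal window 25-39 weeks and infant window
    40-55 weeks, five acquisition sequences.  Parcel/network dimensions
    default to the desk-scale 40/4 configuration; the full 195-parcel,
    8-network atlas is available by setting the fields.
    """

    n_subjects: int = 140
    session_count_weights: dict[int, float] = field(
        default_factory=lambda: dict(STUDY_SESSION_WEIGHTS)
    )
    fetal_age_range: tuple[float, float] = (25.0, 39.0)
    infant_age_range: tuple[float, float] = (40.0, 55.0)
    n_parcels: int = 40
    n_networks: int = 4
    batch_labels: tuple[str, ...] = ("fetal_i", "fetal_ii", "infant_i", "infant_ii", "infant_iii")
    seed: int = 0
    cross_birth_prob: float = 0.6  # P(a multi-session subject spans birth)
    fetal_fraction: float = 126 / 184  # P(single-session subject is fetal)

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be nonnegative")
        w = np.array(list(self.session_count_weights.values()), dtype=float)
        if w.size == 0 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("session_count_weights must be a probability vector")
        if not self.fetal_age_range[1] < self.infant_age_range[0]:
            raise ConfigurationError("fetal age window must end before the infant window starts")
        if self.n_networks > self.n_parcels:
            raise ConfigurationError("n_networks cannot exceed n_parcels")
        if not self.batch_labels:
            raise ConfigurationError("at least one batch label required")


@dataclass(frozen=True)
class EdgeTruth:
    """Ground-truth mean trajectory for one edge (Fisher-z units)."""

    edge_id: int
    shape: str  # sigmoid | linear_up | linear_down | flat
    baseline: float = 0.0
    amplitude: float = 0.0  # sigmoid asymptotic rise
    midpoint: float = 40.0  # weeks; sigmoid inflection
    steepness: float = 1.0  # per week
    slope: float = 0.0  # z-units / week for linear shapes

    def __post_init__(self):
        if self.shape not in {"sigmoid", "linear_up", "linear_down", "flat"}:
            raise ConfigurationError(f"unknown trajectory shape {self.shape!r}")
        if self.shape == "flat" and (self.amplitude != 0 or self.slope != 0):
            raise ConfigurationError("flat truth must have amplitude = slope = 0")


@dataclass
class NoiseModel:
    """Variance structure of simulated edge values.

    subject_sd is the SD of the per-subject random intercept, residual_sd
    the session-level Gaussian noise SD.  Batch effects are additive shifts
    and multiplicative variance scales keyed by sequence label.
    """

    subject_sd: float = 0.1
    residual_sd: float = 0.1
    batch_additive: dict[str, float] = field(default_factory=dict)
    batch_multiplicative: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        if any(v <= 0 for v in self.batch_multiplicative.values()):
            raise ConfigurationError("multiplicative batch scales must be positive")


def edge_mean(truth: EdgeTruth, age) -> np.ndarray | float:
    """Ground-truth mean Fisher-z value of an edge at ``age`` weeks.

    sigmoid: baseline + amplitude / (1 + exp(-steepness*(age - midpoint)))
    linear:  baseline + slope * (age - 25)
    flat:    baseline
    """
    age = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite")
    if truth.shape == "sigmoid":
        out = truth.baseline + truth.amplitude / (
            1.0 + np.exp(-truth.steepness * (age - truth.midpoint))
        )
    elif truth.shape in ("linear_up", "linear_down"):
        out = truth.baseline + truth.slope * (age - AGE_REF_WEEKS)
    else:
        out = truth.baseline + np.zeros_like(age)
    return out if out.ndim else float(out)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a longitudinal cohort table.

    Returns a DataFrame with columns subject_id, session_id, age_weeks,
    cohort (fetal/infant), sequence_id.  Each subject's session ages are
    strictly increasing; multi-session subjects span birth with
    probability ``spec.cross_birth_prob``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = sorted(spec.session_count_weights)
    probs = np.array([spec.session_count_weights[k] for k in counts], dtype=float)
    fetal_batches = [b for b in spec.batch_labels if b.startswith("fetal")]
    infant_batches = [b for b in spec.batch_labels if b.startswith("infant")]
    if not fetal_batches or not infant_batches:
        fetal_batches = infant_batches = list(spec.batch_labels)
    fw = _sequence_weights(fetal_batches, "fetal")
    iw = _sequence_weights(infant_batches, "infant")

    rows = []
    for s in range(spec.n_subjects):
        k = int(rng.choice(counts, p=probs))
        if k == 1:
            n_fetal = int(rng.random() < spec.fetal_fraction)
        elif rng.random() < spec.cross_birth_prob:
            n_fetal = int(rng.integers(1, k))  # at least one on each side of birth
        else:
            n_fetal = k * int(rng.random() < spec.fetal_fraction)
        ages = np.concatenate(
            [
                np.sort(rng.uniform(*spec.fetal_age_range, size=n_fetal)),
                np.sort(rng.uniform(*spec.infant_age_range, size=k - n_fetal)),
            ]
        )
        for j, age in enumerate(ages):
            fetal = j < n_fetal
            pool, w = (fetal_batches, fw) if fetal else (infant_batches, iw)
            rows.append(
                {
                    "subject_id": f"sub-{s:04d}",
                    "session_id": f"ses-{j + 1}",
                    "age_weeks": float(age),
                    "cohort": "fetal" if fetal else "infant",
                    "sequence_id": str(rng.choice(pool, p=w)),
                }
            )
    columns = ["subject_id", "session_id", "age_weeks", "cohort", "sequence_id"]
    return pd.DataFrame(rows, columns=columns)


def _sequence_weights(labels: list[str], cohort: str) -> np.ndarray:
    counts = STUDY_SEQUENCES.get(cohort, {})
    w = np.array([counts.get(lbl, 1.0) for lbl in labels], dtype=float)
    return w / w.sum()


def make_edge_truths(
    n_edges: int,
    seed: int = 0,
    shape_probs: dict[str, float] | None = None,
) -> list[EdgeTruth]:
    """Draw a mixture of edge trajectory families with realistic parameters.

    Default mixture: 40% flat, 25% sigmoid (amplitude 0.2-0.5, midpoint
    ~40 wk, steepness 0.5-1.5/wk), 20% linear increase and 15% linear
    decrease (|slope| 0.005-0.02 z/wk).
    """
    if shape_probs is None:
        shape_probs = {"flat": 0.40, "sigmoid": 0.25, "linear_up": 0.20, "linear_down": 0.15}
    shapes = list(shape_probs)
    probs = np.array([shape_probs[s] for s in shapes], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    truths = []
    for e in range(n_edges):
        shape = str(rng.choice(shapes, p=probs))
        baseline = float(rng.normal(0.1, 0.1))
        if shape == "sigmoid":
            truths.append(
                EdgeTruth(
                    edge_id=e,
                    shape=shape,
                    baseline=baseline,
                    amplitude=float(rng.uniform(0.2, 0.5)),
                    midpoint=float(rng.normal(40.0, 1.5)),
                    steepness=float(rng.uniform(0.5, 1.5)),
                )
            )
        elif shape in ("linear_up", "linear_down"):
            mag = float(rng.uniform(0.005, 0.02))
            truths.append(
                EdgeTruth(
                    edge_id=e,
                    shape=shape,
                    baseline=baseline,
                    slope=mag if shape == "linear_up" else -mag,
                )
            )
        else:
            truths.append(EdgeTruth(edge_id=e, shape="flat", baseline=baseline))
    return truths


@dataclass
class EdgeDataset:
    """Simulated per-session edge values plus the generating ground truth."""

    edges: np.ndarray  # (n_sessions, n_edges) Fisher-z values
    cohort: pd.DataFrame
    truths: list[EdgeTruth]
    noise: NoiseModel
    subject_intercepts: dict[str, np.ndarray]  # subject -> (n_edges,)
    seed: int

    @property
    def n_sessions(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def truth_means(self) -> np.ndarray:
        """Noise-free edge means for every session (same shape as edges)."""
        ages = self.cohort["age_weeks"].to_numpy()
        return np.column_stack([edge_mean(t, ages) for t in self.truths])

    def to_json_sidecar(self) -> str:
        payload = {
            "seed": self.seed,
            "noise": {
                "subject_sd": self.noise.subject_sd,
                "residual_sd": self.noise.residual_sd,
                "batch_additive": self.noise.batch_additive,
                "batch_multiplicative": self.noise.batch_multiplicative,
            },
            "truths": [vars(t) for t in self.truths],
        }
        return json.dumps(payload, indent=2)


def simulate_connectomes(
    cohort: pd.DataFrame,
    truths: list[EdgeTruth],
    noise: NoiseModel,
    seed: int = 0,
) -> EdgeDataset:
    """Simulate per-session edge values under the additive batch model.

    z_edge(session) = edge_mean(age) + u_subject + gamma_batch
                      + sqrt(delta2_batch) * eps

    with u ~ N(0, subject_sd^2) per subject (shared across sessions) and
    eps ~ N(0, residual_sd^2) i.i.d.  Unknown sequence labels in the
    cohort raise a ConfigurationError.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    present = set(cohort["sequence_id"])
    unknown = (set(noise.batch_additive) | set(noise.batch_multiplicative)) - present
    if unknown:
        raise ConfigurationError(f"unknown batch labels in noise model: {sorted(unknown)}")
    n_sessions = len(cohort)
    n_edges = len(truths)
    ages = cohort["age_weeks"].to_numpy()
    means = np.column_stack([edge_mean(t, ages) for t in truths]) if n_edges else np.zeros((n_sessions, 0))

    subjects = cohort["subject_id"].to_numpy()
    intercepts: dict[str, np.ndarray] = {}
    for s in pd.unique(subjects):
        intercepts[s] = rng.normal(0.0, noise.subject_sd, size=n_edges)
    u = np.vstack([intercepts[s] for s in subjects]) if n_sessions else np.zeros((0, n_edges))

    add = cohort["sequence_id"].map(lambda b: noise.batch_additive.get(b, 0.0)).to_numpy()
    mult = cohort["sequence_id"].map(lambda b: noise.batch_multiplicative.get(b, 1.0)).to_numpy()
    eps = rng.normal(0.0, noise.residual_sd, size=(n_sessions, n_edges))
    edges = means + u + add[:, None] + np.sqrt(mult)[:, None] * eps
    return EdgeDataset(
        edges=edges,
        cohort=cohort.reset_index(drop=True),
        truths=truths,
        noise=noise,
        subject_intercepts=intercepts,
        seed=seed,
    )


@dataclass
class SimulatedScan:
    """A synthetic single-run scan fixture for the QC stage."""

    timeseries: np.ndarray  # (n_frames, n_parcels)
    motion: np.ndarray  # (n_frames, 6): 3 translations mm, 3 rotations rad
    masks: np.ndarray  # (n_frames, n_voxels) boolean brain masks
    reference_mask: np.ndarray  # (n_voxels,) boolean
    spike_frames: np.ndarray


def simulate_timeseries(
    n_frames: int,
    n_parcels: int,
    spike_frames=(),
    seed: int = 0,
    baseline: float = 1000.0,
    noise_sd: float = 5.0,
    spike_amplitude: float = 20.0,
    motion_sd: float = 0.02,
    motion_spike_mm: float = 2.0,
    mask_shape: tuple[int, int] = (16, 16),
) -> SimulatedScan:
    """Simulate parcel time series, motion trace and frame masks.

    Spike frames receive a large intensity jump (driving DVARS), a large
    translation step (driving FD) and an eroded brain mask (depressing the
    Dice coefficient against the reference mask), so censoring operations
    have known positives.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    spike_frames = np.asarray(sorted(set(int(f) for f in spike_frames)), dtype=int)
    if spike_frames.size and (spike_frames.min() < 0 or spike_frames.max() >= n_frames):
        raise ValueError("spike_frames outside [0, n_frames)")
    rng = np.random.default_rng(seed)

    ts = baseline + rng.normal(0.0, noise_sd, size=(n_frames, n_parcels))
    ts[spike_frames] += spike_amplitude

    motion = np.zeros((n_frames, 6))
    motion[:, :3] = np.cumsum(rng.normal(0.0, motion_sd, size=(n_frames, 3)), axis=0)
    motion[:, 3:] = np.cumsum(rng.normal(0.0, motion_sd / 50.0, size=(n_frames, 3)), axis=0)
    for f in spike_frames:  # persistent position step: FD spikes at f only
        motion[f:, 0] += motion_spike_mm

    # circular reference mask on a small grid; spikes erode its border
    yy, xx = np.mgrid[0 : mask_shape[0], 0 : mask_shape[1]]
    cy, cx = (mask_shape[0] - 1) / 2, (mask_shape[1] - 1) / 2
    r = min(mask_shape) * 0.4
    ref = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2
    eroded = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (0.6 * r) ** 2
    masks = np.repeat(ref.ravel()[None, :], n_frames, axis=0)
    masks[spike_frames] = eroded.ravel()
    return SimulatedScan(
        timeseries=ts,
        motion=motion,
        masks=masks,
        reference_mask=ref.ravel(),
        spike_frames=spike_frames,
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_edge_dataset(ds: EdgeDataset, edges_path, sidecar_path) -> None:
    """Write sessions x edges TSV plus a JSON ground-truth sidecar."""
    pd.DataFrame(
        ds.edges, columns=[f"edge_{e}" for e in range(ds.n_edges)]
    ).to_csv(edges_path, sep="\t", index=False)
    with open(sidecar_path, "w") as fh:
        fh.write(ds.to_json_sidecar())
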