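import numpy as np
import pytest

from fconntraj import synthetic


@pytest.fixture(scope="session")
def study_cohort():
    """A default-condition synthetic cohort (~140 subjects, 5 sequences)."""
    return synthetic.make_cohort(synthetic.CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def simulate_null_edges(cohort, n_edges, subject_sd=0.1, residual_sd=0.1, seed=0):
    """Flat-truth edge data: subject intercepts + Gaussian noise only."""
    rng = np.random.default_rng(seed)
    subs = cohort["subject_id"].to_numpy()
    labels, inv = np.unique(subs, return_inverse=True)
    u = rng.normal(0.0, subject_sd, (labels.size, n_edges))
    return u[inv] + rng.normal(0.0, residual_sd, (len(cohort), n_edges))
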