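"""Edge-wise age effects, FDR, averaging, pairs and QC-FC diagnostics."""

import numpy as np
import pandas as pd
import pytest

from fconntraj import effects as fx
from fconntraj import synthetic
from fconntraj.connectome import Atlas, edge_index
from fconntraj.synthetic import CohortSpec, EdgeTruth, NoiseModel
from tests.conftest import simulate_null_edges


class TestEdgewiseAgeModel:
    def test_noiseless_linear_slope_exact(self, study_cohort):
        ages = study_cohort["age_weeks"].to_numpy()
        edges = (0.1 + 0.01 * (ages - 25))[:, None]
        eff = fx.edgewise_age_model(edges, study_cohort)
        assert eff["beta"][0] == pytest.approx(0.01, abs=1e-8)

    def test_slope_recovery_within_3se(self, study_cohort):
        truths = [EdgeTruth(e, "linear_up", baseline=0.0, slope=0.01) for e in range(100)]
        ds = synthetic.simulate_connectomes(
            study_cohort, truths, NoiseModel(subject_sd=0.1, residual_sd=0.1), seed=2
        )
        eff = fx.edgewise_age_model(ds.edges, study_cohort)
        pull = (eff["beta"] - 0.01) / eff["se"]
        assert abs(pull.mean()) < 3 / np.sqrt(len(eff))

    def test_strong_effect_sign_classification(self, study_cohort):
        truths = [
            EdgeTruth(e, "linear_up" if e % 2 == 0 else "linear_down",
                      slope=0.02 if e % 2 == 0 else -0.02)
            for e in range(40)
        ]
        ds = synthetic.simulate_connectomes(
            study_cohort, truths, NoiseModel(subject_sd=0.05, residual_sd=0.05), seed=3
        )
        eff = fx.edgewise_age_model(ds.edges, study_cohort)
        sig = eff[eff["sign"] != "null"]
        assert len(sig) > 0.9 * len(eff)
        truth_sign = np.where(np.arange(40) % 2 == 0, "positive", "negative")
        match = (sig["sign"].to_numpy() == truth_sign[sig["edge_id"]]).mean()
        assert match >= 0.95

    def test_subset_restricts_to_cohort(self, study_cohort):
        edges = simulate_null_edges(study_cohort, 5, seed=4)
        eff = fx.edgewise_age_model(edges, study_cohort, subset="fetal")
        assert len(eff) == 5  # runs on the fetal subset alone

    def test_too_few_subjects_rejected(self):
        coh = pd.DataFrame(
            {"subject_id": ["a", "a"], "age_weeks": [30.0, 45.0],
             "cohort": ["fetal", "infant"], "sequence_id": ["x", "x"]}
        )
        with pytest.raises(ValueError):
            fx.edgewise_age_model(np.zeros((2, 1)), coh)


class TestFdrBH:
    def test_hand_step_up_all_rejected(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        reject, q = fx.fdr_bh(p, 0.05)
        assert reject.all()  # p(k) <= k*0.05/5 holds at k=5, step-up takes all

    def test_all_ones_none_rejected(self):
        reject, q = fx.fdr_bh(np.ones(10))
        assert not reject.any() and np.allclose(q, 1.0)

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fx.fdr_bh(np.array([0.04]), 0.05)
        assert reject[0]

    def test_q_values_monotone_and_above_p(self, rng):
        p = rng.uniform(size=50)
        _, q = fx.fdr_bh(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_nan_excluded_with_warning(self):
        p = np.array([0.01, np.nan, 0.9])
        with pytest.warns(UserWarning, match="NaN"):
            reject, q = fx.fdr_bh(p)
        assert not reject[1] and np.isnan(q[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fx.fdr_bh(np.array([1.2]))


class TestAverageSignificant:
    def _effects(self, signs):
        return pd.DataFrame({"edge_id": np.arange(len(signs)), "sign": signs})

    def test_single_edge_series_identity(self, rng):
        edges = rng.normal(size=(6, 3))
        eff = self._effects(["positive", "null", "null"])
        np.testing.assert_allclose(fx.average_significant(edges, eff, "positive"), edges[:, 0])

    def test_two_edges_averaged(self, rng):
        edges = rng.normal(size=(6, 2))
        eff = self._effects(["negative", "negative"])
        np.testing.assert_allclose(
            fx.average_significant(edges, eff, "negative"), edges.mean(axis=1)
        )

    def test_empty_set_nan_with_warning(self, rng):
        edges = rng.normal(size=(4, 2))
        eff = self._effects(["null", "null"])
        with pytest.warns(UserWarning):
            out = fx.average_significant(edges, eff, "positive")
        assert np.isnan(out).all()

    def test_sigmoid_truth_series_increases_across_birth(self, study_cohort):
        truths = [
            EdgeTruth(e, "sigmoid", baseline=0.0, amplitude=0.4, midpoint=40, steepness=1.0)
            for e in range(20)
        ]
        ds = synthetic.simulate_connectomes(
            study_cohort, truths, NoiseModel(subject_sd=0.02, residual_sd=0.02), seed=5
        )
        eff = fx.edgewise_age_model(ds.edges, study_cohort)
        series = fx.average_significant(ds.edges, eff, "positive")
        fetal = series[(study_cohort["cohort"] == "fetal").to_numpy()]
        infant = series[(study_cohort["cohort"] == "infant").to_numpy()]
        assert infant.mean() > fetal.mean() + 0.2


class TestNetworkPairs:
    def test_eight_networks_give_36_pairs(self):
        assert len(fx.network_pairs(Atlas.synthetic(195, 8))) == 36

    def test_two_networks_give_3_pairs(self):
        assert len(fx.network_pairs(Atlas.synthetic(4, 2))) == 3

    def test_every_edge_in_exactly_one_pair(self, study_cohort):
        atlas = Atlas.synthetic(12, 3)
        edges = simulate_null_edges(study_cohort, 66, seed=6)
        eff = fx.edgewise_age_model(edges, study_cohort)
        eff["sign"] = "positive"  # force all edges significant
        tab = fx.network_pair_series(edges, eff, atlas)
        per_pair = tab.groupby("pair")["n_edges"].first()
        assert per_pair.sum() == 66
        assert len(per_pair) == 6  # 3 networks -> 6 pairs

    def test_all_null_pair_flagged_missing(self, study_cohort):
        atlas = Atlas.synthetic(4, 2)
        edges = simulate_null_edges(study_cohort, 6, seed=7)
        eff = pd.DataFrame({"edge_id": np.arange(6), "sign": ["null"] * 6})
        tab = fx.network_pair_series(edges, eff, atlas)
        assert tab["value"].isna().all()
        assert (tab["n_edges"] == 0).all()


class TestDistances:
    def test_coincident_parcels_zero(self):
        coords = np.zeros((3, 3))
        np.testing.assert_allclose(fx.edge_distance(coords), 0.0)

    def test_pythagoras(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4, 0]])
        assert fx.edge_distance(coords)[0] == pytest.approx(5.0)

    def test_missing_coordinates_rejected(self):
        coords = np.array([[0.0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError):
            fx.edge_distance(coords)

    def test_identical_distributions_non_significant(self, rng):
        n = 200
        eff = pd.DataFrame(
            {"edge_id": np.arange(n), "sign": ["positive"] * 100 + ["negative"] * 100}
        )
        distances = np.tile(rng.uniform(10, 100, 100), 2)  # same values in both sets
        out = fx.compare_distance_distributions(eff, distances)
        assert out["p"] > 0.95


class TestQcFc:
    def _cohort_edges(self, n_sessions, n_edges, seed):
        rng = np.random.default_rng(seed)
        edges = rng.normal(size=(n_sessions, n_edges))
        fd = rng.uniform(0.05, 0.5, n_sessions)
        coords = rng.normal(scale=40, size=((int(np.ceil((1 + np.sqrt(1 + 8 * n_edges)) / 2))), 3))
        from fconntraj.connectome import n_edges as ne

        P = coords.shape[0]
        assert ne(P) >= n_edges
        dist = fx.edge_distance(coords)[:n_edges]
        return edges, fd, dist

    def test_independent_motion_near_zero(self):
        edges, fd, dist = self._cohort_edges(60, 500, seed=8)
        assert abs(fx.qcfc_distance(edges, fd, dist)) < 0.1

    def test_distance_dependent_artifact_detected(self):
        edges, fd, dist = self._cohort_edges(60, 500, seed=9)
        # motion artifact strongest at short distances, above the 0.05-SD noise
        edges = 0.05 * edges + np.outer(fd, 5.0 / (dist + 5.0))
        assert fx.qcfc_distance(edges, fd, dist) < -0.3

    def test_two_sessions_rejected(self):
        with pytest.raises(ValueError):
            fx.qcfc_distance(np.zeros((2, 10)), np.array([0.1, 0.2]), np.ones(10))

    def test_constant_motion_rejected(self):
        with pytest.raises(ValueError):
            fx.qcfc_distance(np.zeros((5, 10)), np.full(5, 0.2), np.ones(10))
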