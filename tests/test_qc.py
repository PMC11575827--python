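"""QC statistics and censoring/exclusion rules: hand-computed cases and
invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fconntraj import qc
from fconntraj.synthetic import simulate_timeseries


class TestFramewiseDisplacement:
    def test_identical_frames_zero(self):
        assert qc.framewise_displacement(np.zeros((5, 6))).max() == 0

    def test_translation_step(self):
        m = np.zeros((3, 6))
        m[1, 0] = 0.1  # 0.1 mm x-translation at frame 1
        fd = qc.framewise_displacement(m)
        np.testing.assert_allclose(fd, [0.0, 0.1, 0.1])

    def test_rotation_step_at_50mm_radius(self):
        m = np.zeros((2, 6))
        m[1, 3] = 0.01  # 0.01 rad -> 50 * 0.01 = 0.5 mm
        assert qc.framewise_displacement(m)[1] == pytest.approx(0.5)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            qc.framewise_displacement(np.zeros((1, 6)))


class TestDvars:
    def test_constant_series_zero(self):
        assert qc.dvars(np.full((10, 4), 7.0)).max() == 0

    def test_two_voxel_step(self):
        # (0,0) -> (3,4): sqrt((9+16)/2) = sqrt(12.5)
        ts = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert qc.dvars(ts)[1] == pytest.approx(np.sqrt(12.5))

    def test_homogeneity(self, rng):
        ts = rng.normal(size=(20, 5))
        np.testing.assert_allclose(qc.dvars(3.5 * ts), 3.5 * qc.dvars(ts))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qc.dvars(np.empty((0, 3)))


class TestDice:
    def test_identical_masks(self):
        m = np.array([1, 1, 0, 1], dtype=bool)
        assert qc.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        assert qc.dice(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_half_overlap(self):
        a = np.array([1, 1, 1, 1, 0, 0])
        b = np.array([1, 1, 0, 0, 1, 1])
        assert qc.dice(a, b) == pytest.approx(0.5)  # 2*2 / (4+4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qc.dice(np.zeros(3), np.zeros(4))

    def test_empty_masks_defined_as_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert qc.dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0


class TestCensorFetal:
    def test_all_clean_nothing_censored(self):
        n = 50
        res = qc.censor_fetal(np.ones(n), np.full(n, 0.1), np.full(n, 30.0))
        assert res.n_retained == n

    def test_low_dice_frame_censored(self):
        dice = np.ones(20)
        dice[7] = 0.85
        res = qc.censor_fetal(dice, np.full(20, 0.1), np.full(20, 30.0))
        assert not res.keep[7] and res.reasons[7] == {"dice"}
        assert res.n_retained == 19

    def test_fixed_fd_override(self, rng):
        fd = rng.normal(0.2, 0.05, 200).clip(0)
        fd[13] = 1.6
        res = qc.censor_fetal(
            np.ones(200), fd, np.full(200, 30.0), qc.CensorPolicy(fd_fixed=1.5)
        )
        assert set(np.flatnonzero(~res.keep)) == {13}
        assert res.reasons[13] == {"fd"}

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            qc.censor_fetal(np.array([]), np.array([]), np.array([]))

    def test_idempotent_with_fixed_thresholds(self, rng):
        fd = rng.normal(0.2, 0.05, 100).clip(0)
        fd[[5, 50]] = 2.0
        dv = np.full(100, 30.0)
        policy = qc.CensorPolicy(fd_fixed=1.5, dvars_fixed=132.69)
        first = qc.censor_fetal(np.ones(100), fd, dv, policy)
        again = qc.censor_fetal(
            np.ones(first.n_retained), fd[first.keep], dv[first.keep], policy
        )
        assert again.n_retained == first.n_retained


class TestCensorInfant:
    def test_expansion_window(self):
        dv = np.zeros(20)
        dv[10] = 60.0
        res = qc.censor_infant(dv)
        assert set(np.flatnonzero(~res.keep)) == {9, 10, 11, 12}
        assert res.reasons[10] == {"dvars"}
        assert res.reasons[9] == {"expansion"}

    def test_window_clipped_at_run_start(self):
        dv = np.zeros(10)
        dv[0] = 60.0
        res = qc.censor_infant(dv)
        assert set(np.flatnonzero(~res.keep)) == {0, 1, 2}

    def test_adjacent_outliers_union(self):
        dv = np.zeros(20)
        dv[[5, 6]] = 60.0
        res = qc.censor_infant(dv)
        assert set(np.flatnonzero(~res.keep)) == {4, 5, 6, 7, 8}

    @given(
        st.lists(st.integers(min_value=0, max_value=29), max_size=6),
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=0, max_value=4),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_expansion_never_leaves_run(self, outliers, before, after):
        dv = np.zeros(30)
        dv[list(set(outliers))] = 60.0
        res = qc.censor_infant(dv, before=before, after=after)
        # flags defined exactly on [0, n) and censored set matches windows
        expected = set()
        for t in set(outliers):
            expected |= set(range(max(0, t - before), min(30, t + after + 1)))
        assert set(np.flatnonzero(~res.keep)) == expected


class TestExcludeScan:
    def test_too_few_retained_frames(self):
        keep = np.ones(120, bool)
        keep[:20] = False  # 100 retained < 105
        res = qc.CensorResult(keep=keep, reasons=[set() if k else {"fd"} for k in keep])
        dec = qc.exclude_scan(res, np.zeros((120, 6)))
        assert dec.excluded and dec.reasons == {"too_few_frames"}

    def test_clean_scan_not_excluded(self, rng):
        keep = np.ones(200, bool)
        motion = np.column_stack(
            [rng.normal(0, 0.01, (200, 3)), rng.normal(0, 1e-4, (200, 3))]
        )
        res = qc.CensorResult(keep=keep, reasons=[set()] * 200)
        assert not qc.exclude_scan(res, motion).excluded

    def test_peak_translation_excludes(self):
        motion = np.zeros((200, 6))
        motion[50, 0] = 1.2
        res = qc.CensorResult(keep=np.ones(200, bool), reasons=[set()] * 200)
        dec = qc.exclude_scan(res, motion)
        assert dec.excluded and "high_motion_max" in dec.reasons

    def test_motion_on_retained_frames_only(self):
        motion = np.zeros((200, 6))
        motion[50, 0] = 5.0  # huge, but censored
        keep = np.ones(200, bool)
        keep[50] = False
        res = qc.CensorResult(keep=keep, reasons=[{"fd"} if not k else set() for k in keep])
        assert not qc.exclude_scan(res, motion).excluded


class TestTsnr:
    def test_constant_series_undefined(self):
        out = qc.tsnr(np.full((10, 2), 5.0))
        assert np.isnan(out).all()

    def test_known_mean_over_sd(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)  # sample mean 0, sample SD 1
        ts = (100.0 + 10.0 * x)[:, None]  # mean 100, SD 10 -> tSNR 10
        assert qc.tsnr(ts)[0] == pytest.approx(10.0)

    def test_offset_shift_property(self, rng):
        ts = rng.normal(50, 5, size=(40, 3))
        sd = ts.std(axis=0, ddof=1)
        np.testing.assert_allclose(qc.tsnr(ts + 7.0), qc.tsnr(ts) + 7.0 / sd)


class TestSpikeDetection:
    def test_perfect_sensitivity_specificity_for_large_spikes(self):
        # a motion spike is a translation step, so FD flags exactly that frame
        scan = simulate_timeseries(150, 8, spike_frames=[20, 90, 121], seed=5)
        fd = qc.framewise_displacement(scan.motion)
        res = qc.censor_fetal(
            np.ones(150), fd, np.zeros(150), qc.CensorPolicy(fd_fixed=1.0, dvars_fixed=50.0)
        )
        assert set(np.flatnonzero(~res.keep)) == {20, 90, 121}


def test_sample_accounting_reproduces_study_numbers():
    """140 fetal - (3+5+3+3) = 126; 63 infant - (1+2+2) = 58."""
    final = qc.sample_accounting()
    assert final == {"fetal": 126, "infant": 58}
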