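"""Percent-change epoching, group contrasts, conjunction/disjunction
algebra, eye-movement-signal removal, voxel selection, k-means network
partitioning, and ROI timecourses."""
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from noreport import clusterstat as cs
from noreport import fmri
from noreport.synth import BoldTemplateSet, generate_fmri_session


@pytest.fixture(scope="module")
def contrast_result():
    """A shared report-cohort contrast on the default grid (20 participants)."""
    tpl = BoldTemplateSet()
    sess = generate_fmri_session(20, 30, tpl, "report", seed=1)
    res = fmri.group_contrast_map(
        sess.perceived, sess.not_perceived,
        cs.ClusterTestConfig(n_perm=300, seed=2),
    )
    return tpl, sess, res


class TestPercentChange:
    def test_definition(self):
        bold = np.full((1, 1, 1, 100), 100.0)
        bold[0, 0, 0, 50] = 102.0
        epochs, times, ok = fmri.percent_change_epochs(
            bold, [50.0], tr=1.0, epoch_window=(-5, 5)
        )
        assert ok.all()
        assert epochs[0, 0, times == 0][0] == pytest.approx(2.0)

    def test_constant_series_zero(self):
        bold = np.full((2, 2, 1, 80), 500.0)
        epochs, _, _ = fmri.percent_change_epochs(
            bold, [40.0], epoch_window=(-10, 10)
        )
        np.testing.assert_allclose(epochs, 0.0)

    def test_nonpositive_baseline_masked(self):
        bold = np.full((2, 1, 1, 80), 100.0)
        bold[1, 0, 0, :] = 0.0
        with pytest.warns(UserWarning, match="non-positive baseline"):
            _, _, ok = fmri.percent_change_epochs(
                bold, [40.0], epoch_window=(-10, 10)
            )
        assert ok.tolist() == [True, False]

    def test_event_near_edge_rejected(self):
        bold = np.full((1, 1, 1, 50), 100.0)
        with pytest.raises(ValueError, match="edge"):
            fmri.percent_change_epochs(bold, [10.0], epoch_window=(-20, 20))

    def test_template_amplitude_roundtrip_through_run(self):
        # noiseless continuous run -> epoching recovers the template peak
        from noreport.synth import generate_fmri_run

        tpl = BoldTemplateSet(noise_sd=0.0, das_amp=1.0, das_peak=3.0)
        run = generate_fmri_run(
            "report", "testing", tpl, seed=0, noise_sd=0.0,
            event_onsets=[100.0],
        )
        epochs, times, ok = fmri.percent_change_epochs(run, [100.0], tr=tpl.tr)
        das = tpl.network_masks()["DAS"]
        peak = epochs[0][das][:, times == 3.0].mean()
        assert peak == pytest.approx(1.0, abs=1e-6)


class TestGroupContrast:
    def test_identical_sets_no_clusters(self):
        tpl = BoldTemplateSet()
        sess = generate_fmri_session(8, 10, tpl, "report", seed=3)
        res = fmri.group_contrast_map(
            sess.perceived, sess.perceived,
            cs.ClusterTestConfig(n_perm=150, seed=4),
        )
        assert res.significant_clusters() == []

    def test_networks_detected_with_correct_signs(self, contrast_result):
        tpl, sess, res = contrast_result
        masks = tpl.network_masks()
        t = tpl.times
        pos3 = res.significant_mask[:, t == 3.0].ravel() & (
            res.t_map[:, t == 3.0].ravel() > 0
        )
        assert pos3[masks["DAS"]].mean() >= 0.8
        neg6 = res.significant_mask[:, t == 6.0].ravel() & (
            res.t_map[:, t == 6.0].ravel() < 0
        )
        assert neg6[masks["DMN"]].mean() >= 0.8


class TestConjunctionDisjunction:
    def _fake_result(self, tmap, sig):
        return cs.ClusterTestResult(
            t_map=tmap, clusters=[], significant_mask=sig,
            null_max_mass=np.array([]), alpha=0.05, threshold_t=2.0,
            times=np.arange(tmap.shape[1], dtype=float),
            space_shape=(tmap.shape[0],),
        )

    def test_signed_conjunction_rules(self):
        t_a = np.array([[3.0, 3.0, -3.0]])
        t_b = np.array([[3.0, -3.0, -3.0]])
        sig = np.ones((1, 3), dtype=bool)
        cm = fmri.conjunction_map(
            self._fake_result(t_a, sig), self._fake_result(t_b, sig)
        )
        assert cm.shared_increase.tolist() == [[True, False, False]]
        assert cm.shared_decrease.tolist() == [[False, False, True]]

    def test_conjunction_idempotent_and_commutative(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=(10, 4))
        sig = rng.random((10, 4)) < 0.4
        a = self._fake_result(t, sig)
        cm = fmri.conjunction_map(a, a)
        pos, neg = sig & (t > 0), sig & (t < 0)
        np.testing.assert_array_equal(cm.shared_increase, pos)
        np.testing.assert_array_equal(cm.shared_decrease, neg)
        t2 = rng.normal(size=(10, 4))
        sig2 = rng.random((10, 4)) < 0.4
        b = self._fake_result(t2, sig2)
        ab = fmri.conjunction_map(a, b)
        ba = fmri.conjunction_map(b, a)
        np.testing.assert_array_equal(ab.shared_increase, ba.shared_increase)

    def test_disjoint_sets_returned_intact(self):
        t = np.full((4, 2), 3.0)
        sig_a = np.zeros((4, 2), bool)
        sig_a[:2] = True
        sig_b = np.zeros((4, 2), bool)
        sig_b[2:] = True
        out = fmri.exclusive_disjunction_map(
            self._fake_result(t, sig_a), self._fake_result(t, sig_b)
        )
        np.testing.assert_array_equal(out["only_A"]["increase"], sig_a)
        np.testing.assert_array_equal(out["only_B"]["increase"], sig_b)

    def test_subset_gives_empty_only_a(self):
        t = np.full((4, 2), 3.0)
        sig_a = np.zeros((4, 2), bool)
        sig_a[0] = True
        sig_b = np.ones((4, 2), bool)
        out = fmri.exclusive_disjunction_map(
            self._fake_result(t, sig_a), self._fake_result(t, sig_b)
        )
        assert not out["only_A"]["increase"].any()

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_of_union_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        t_a = rng.normal(size=(12, 5))
        t_b = rng.normal(size=(12, 5))
        sig_a = rng.random((12, 5)) < 0.5
        sig_b = rng.random((12, 5)) < 0.5
        a, b = self._fake_result(t_a, sig_a), self._fake_result(t_b, sig_b)
        cm = fmri.conjunction_map(a, b)
        dj = fmri.exclusive_disjunction_map(a, b)
        for sign, key in (("increase", 1), ("decrease", -1)):
            pa = sig_a & (key * t_a > 0)
            pb = sig_b & (key * t_b > 0)
            union = pa | pb
            shared = getattr(cm, f"shared_{sign}")
            only_a = dj["only_A"][sign]
            only_b = dj["only_B"][sign]
            np.testing.assert_array_equal(shared | only_a | only_b, union)
            assert not (shared & only_a).any()
            assert not (shared & only_b).any()
            assert not (only_a & only_b).any()

    def test_grid_mismatch_rejected(self):
        a = self._fake_result(np.zeros((4, 2)), np.zeros((4, 2), bool))
        b = self._fake_result(np.zeros((5, 2)), np.zeros((5, 2), bool))
        with pytest.raises(ValueError, match="grid"):
            fmri.conjunction_map(a, b)


class TestEyeMovementRemoval:
    def _setup(self, pupil_voxel_shared=True, seed=6):
        """No-report difference epochs with a DAS-like effect plus one extra
        voxel region whose effect is pupil-driven (present identically in
        the pupil-sorted difference)."""
        rng = np.random.default_rng(seed)
        grid = (8, 8, 4)
        nv = int(np.prod(grid))
        times = np.arange(-5.0, 11.0)
        n_p = 14
        bump = np.clip(1 - np.abs(times - 3.0) / 3.0, 0, None)
        perception_vox = np.zeros(nv, bool)
        perception_vox[:40] = True
        pupil_vox = np.zeros(nv, bool)
        pupil_vox[60:80] = True
        noise = lambda: 0.25 * rng.standard_normal((n_p, nv, len(times)))
        nore = noise()
        nore[:, perception_vox] += bump
        pupil_effect = np.zeros((nv, len(times)))
        if pupil_voxel_shared:
            pupil_effect[pupil_vox] = bump
        nore[:, pupil_vox] += bump
        sorted_diffs = {
            "pupil": noise() + pupil_effect[None],
            "blink": noise(),
            "msacc": noise(),
        }
        return nore, sorted_diffs, grid, times, perception_vox, pupil_vox

    def test_null_sorted_sets_leave_noreport_mask(self):
        # exactly-zero subtrahends: each contrast reduces to the no-report
        # test itself, so the conjunction returns the no-report mask intact
        nore, _, grid, times, perception_vox, pupil_vox = self._setup()
        zeros = {m: np.zeros_like(nore) for m in ("pupil", "blink", "msacc")}
        cfg = cs.ClusterTestConfig(n_perm=200, seed=0)
        cm = fmri.remove_eye_movement_signals(nore, zeros, grid, times, cfg)
        nr_pos = cm.source_masks["no_report"]["increase"]
        np.testing.assert_array_equal(cm.shared_increase, nr_pos)

    def test_pupil_driven_voxels_removed_and_subset_property(self):
        nore, sorted_diffs, grid, times, perception_vox, pupil_vox = self._setup()
        cfg = cs.ClusterTestConfig(n_perm=200, seed=1)
        cm = fmri.remove_eye_movement_signals(nore, sorted_diffs, grid, times, cfg)
        nr_pos = cm.source_masks["no_report"]["increase"]
        # output always a subset of the no-report significant mask
        assert not (cm.shared_increase & ~nr_pos).any()
        # the planted pupil-driven region is essentially deleted (cluster
        # membership can leak isolated chance points from a neighboring
        # genuine cluster), while the perception-driven region stays
        before = nr_pos[pupil_vox].sum()
        after = cm.shared_increase[pupil_vox].sum()
        assert before > 0
        assert after <= 0.1 * before
        kept = cm.shared_increase[perception_vox].sum()
        assert kept >= 0.5 * nr_pos[perception_vox].sum()


class TestNetworkPartition:
    def test_select_voxels_window_rule(self):
        times = np.arange(-2.0, 15.0)
        sig = np.zeros((3, len(times)), bool)
        sig[0, times == 5.0] = True
        sig[1, times == 12.0] = True  # outside (0, 10]
        res = cs.ClusterTestResult(
            t_map=np.ones((3, len(times))), clusters=[], significant_mask=sig,
            null_max_mass=np.array([]), alpha=0.05, threshold_t=2.0,
            times=times, space_shape=(3,),
        )
        sel = fmri.select_network_voxels(res)
        assert sel.tolist() == [True, False, False]
        # brute-force scan oracle
        win = (times > 0) & (times <= 10)
        brute = np.array([sig[v, win].any() for v in range(3)])
        np.testing.assert_array_equal(sel, brute)

    def test_pure_templates_perfect_partition(self):
        tpl = BoldTemplateSet()
        t = tpl.times
        win = (t > 0) & (t <= 10)
        tcs = tpl.network_timecourses()
        X = np.concatenate(
            [np.tile(tcs[k][win], (5, 1)) for k in ("DAS", "TPN", "DMN")]
        )
        part = fmri.kmeans_networks(X, t[win], seed=0)
        want = ["DAS"] * 5 + ["TPN"] * 5 + ["DMN"] * 5
        assert part.labels.tolist() == want
        assert 3.0 <= part.times[np.argmax(part.cluster_timecourses["DAS"])] <= 4.0
        assert part.times[np.argmax(part.cluster_timecourses["TPN"])] == pytest.approx(6.0)
        assert 6.0 <= part.times[np.argmin(part.cluster_timecourses["DMN"])] <= 8.0

    def test_noisy_recovery_snr2_over_seeds(self):
        """600 voxels at participant-level SNR 2 (template peak / noise SD
        = 2), clustered -- as in the analysis -- on the across-participant
        (N = 20) average, so per-voxel noise is (peak/2)/sqrt(20):
        >= 95% label agreement and ARI >= 0.9 over 20 seeds."""
        tpl = BoldTemplateSet()
        n_participants = 20
        t = tpl.times
        win = (t > 0) & (t <= 10)
        tcs = tpl.network_timecourses()
        truth = np.array(["DAS"] * 200 + ["TPN"] * 200 + ["DMN"] * 200)
        agrees, aris = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.concatenate(
                [np.tile(tcs[k][win], (200, 1)) for k in ("DAS", "TPN", "DMN")]
            )
            sds = np.concatenate(
                [
                    np.full(200, np.abs(tcs[k][win]).max() / 2.0)
                    for k in ("DAS", "TPN", "DMN")
                ]
            ) / np.sqrt(n_participants)
            X = X + sds[:, None] * rng.standard_normal(X.shape)
            part = fmri.kmeans_networks(X, t[win], seed=seed)
            agrees.append(np.mean(part.labels == truth))
            aris.append(adjusted_rand_score(truth, part.labels.astype(str)))
        assert np.mean(agrees) >= 0.95
        assert np.mean(aris) >= 0.9

    def test_too_few_distinct_timecourses(self):
        X = np.tile(np.arange(10.0), (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            fmri.kmeans_networks(X, np.arange(10.0))

    def test_generator_loop_ari(self, contrast_result):
        """Selected-voxel partition vs the generator's ground-truth masks
        (ARI computed over the true network voxels)."""
        tpl, sess, res = contrast_result
        masks = tpl.network_masks()
        sel = fmri.select_network_voxels(res)
        t = tpl.times
        win = (t > 0) & (t <= 10)
        diff = sess.difference.mean(axis=0)
        part = fmri.kmeans_networks(
            diff[sel][:, win], t[win], voxel_indices=np.flatnonzero(sel), seed=3
        )
        truth_all = np.select(
            [masks["DAS"], masks["TPN"], masks["DMN"]],
            ["DAS", "TPN", "DMN"], default="",
        )
        in_truth = truth_all[part.voxel_indices] != ""
        ari = adjusted_rand_score(
            truth_all[part.voxel_indices][in_truth],
            part.labels[in_truth].astype(str),
        )
        assert ari >= 0.9
        assert np.mean(
            part.labels[in_truth] == truth_all[part.voxel_indices][in_truth]
        ) >= 0.95


class TestRoiTimecourse:
    def test_roi_inside_das_all_das(self, contrast_result):
        tpl, sess, res = contrast_result
        masks = tpl.network_masks()
        sel = fmri.select_network_voxels(res)
        t = tpl.times
        win = (t > 0) & (t <= 10)
        diff = sess.difference.mean(axis=0)
        part = fmri.kmeans_networks(
            diff[sel][:, win], t[win], voxel_indices=np.flatnonzero(sel), seed=4
        )
        roi = masks["DAS"]
        out = fmri.roi_timecourse(sess.perceived, roi, part)
        assert out["network_fractions"]["DAS"] > 95.0
        total = sum(out["network_fractions"].values())
        assert total == pytest.approx(100.0)

    def test_single_voxel_roi(self):
        data = np.arange(24, dtype=float).reshape(1, 4, 6)
        roi = np.zeros(4, bool)
        roi[2] = True
        out = fmri.roi_timecourse(data, roi)
        np.testing.assert_array_equal(out["timecourse"], data[0, 2])

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fmri.roi_timecourse(np.zeros((1, 4, 6)), np.zeros(4, bool))
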