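"""Generative models: observer responses, eye sessions, EEG epochs, BOLD
sessions, and ISI segments, plus the generators' seeding/linearity/Poisson
invariants."""
import numpy as np
import pytest
from scipy import stats

from noreport import erp, paradigm as pg
from noreport.erp import peak_latency
from noreport.synth import (
    BoldTemplateSet,
    ErpComponent,
    ErpTemplateSet,
    EyeDynamicsParams,
    ObserverModel,
    default_bold_templates,
    default_erp_templates,
    generate_eeg_epochs,
    generate_eye_session,
    generate_fmri_session,
    generate_isi_segments,
    generate_observer_responses,
    noiseless_epoch,
)
from noreport.synth import testing_run_volume_count as run_volume_count

from conftest import make_schedule


class TestObserver:
    def test_step_function_limit(self):
        obs = ObserverModel(0.13, slope=np.inf)
        sched = make_schedule(2)
        sched[0].opacity = 0.20
        sched[1].opacity = 0.05
        out = generate_observer_responses(sched, obs, seed=0)
        assert out[0][1] is True and out[1][1] is False

    def test_probability_half_at_threshold(self):
        obs = ObserverModel(0.10, slope=40)
        assert obs.p_seen(0.10) == pytest.approx(0.5)

    def test_monotone_in_opacity(self):
        obs = ObserverModel(0.10, slope=25, lapse_rate=0.02, guess_rate=0.03)
        p = obs.p_seen(np.linspace(0, 1, 50))
        assert np.all(np.diff(p) >= -1e-12)

    def test_empirical_rate_at_threshold(self):
        obs = ObserverModel(0.10, slope=40)
        sched = make_schedule(10_000, spacing=1.0)
        for e in sched:
            e.opacity = 0.10
        seen = [s for _, s in generate_observer_responses(sched, obs, seed=1)]
        se = np.sqrt(0.25 / len(seen))
        assert abs(np.mean(seen) - 0.5) < 3 * se

    def test_blank_seen_only_at_guess_rate(self):
        obs = ObserverModel(0.10, slope=40, guess_rate=0.1)
        blanks = [
            pg.StimulusEvent(onset=float(i), location_set="quadrant", location=1,
                             opacity_condition="blank", opacity=0.0)
            for i in range(4000)
        ]
        seen = [s for _, s in generate_observer_responses(blanks, obs, seed=2)]
        se = np.sqrt(0.1 * 0.9 / len(seen))
        assert abs(np.mean(seen) - 0.1) < 3 * se

    def test_opacity_out_of_range_rejected(self):
        obs = ObserverModel(0.10)
        with pytest.raises(ValueError):
            obs.p_seen(1.2)


class TestEyeSession:
    def test_zero_events_stationary_baseline_blink_rate(self):
        params = EyeDynamicsParams()
        rec = generate_eye_session([], [], params, seed=3, tail=400.0)
        lam = params.blink_rate_base * rec.duration
        assert abs(len(rec.info["blink_times"]) - lam) < 3 * np.sqrt(lam)
        assert abs(rec.pupil.mean() - params.pupil_baseline) < 0.2 * params.pupil_baseline

    def test_noiseless_pupil_peak_at_latency(self):
        params = EyeDynamicsParams(
            noise_sd=0, drift_sd=0, blink_rate_base=0, msacc_rate_base=0
        )
        sched = make_schedule(1)
        rec = generate_eye_session(sched, [True], params, seed=4)
        peak_t = rec.time[np.argmax(rec.pupil)]
        assert peak_t == pytest.approx(
            sched[0].onset + params.pupil_peak_latency, abs=2 / params.sampling_rate
        )

    def test_microsaccade_suppression_monte_carlo(self):
        # 200 perceived vs 200 not perceived: post-event msacc counts lower
        # for perceived (one-sided rank test on the generator's own truth)
        params = EyeDynamicsParams(blink_rate_base=0.0)
        sched = make_schedule(400, spacing=8.0)
        labels = [True] * 200 + [False] * 200
        rec = generate_eye_session(sched, labels, params, seed=5)
        ms = rec.info["msacc_times"]
        w0, w1 = params.msacc_suppression_window
        counts = [
            np.count_nonzero((ms >= e.onset + w0) & (ms < e.onset + w1))
            for e in sched
        ]
        res = stats.mannwhitneyu(
            counts[:200], counts[200:], alternative="less"
        )
        assert res.pvalue < 0.01

    def test_blink_rate_poisson_calibration(self):
        # realized counts in windows match the integrated base rate (3 SE)
        params = EyeDynamicsParams()
        rec = generate_eye_session([], [], params, seed=6, tail=1000.0)
        lam = params.blink_rate_base * rec.duration
        n = len(rec.info["blink_times"])
        assert abs(n - lam) < 3 * np.sqrt(lam)

    def test_identical_seed_bit_identical(self):
        sched = make_schedule(5)
        labels = [True, False, True, False, True]
        a = generate_eye_session(sched, labels, seed=7)
        b = generate_eye_session(sched, labels, seed=7)
        np.testing.assert_array_equal(a.pupil, b.pupil)
        np.testing.assert_array_equal(a.gaze_x, b.gaze_x)
        np.testing.assert_array_equal(a.valid, b.valid)

    def test_close_events_warn(self):
        sched = make_schedule(2, spacing=3.0)
        with pytest.warns(UserWarning, match="overlap"):
            generate_eye_session(sched, [True, True], seed=8)

    def test_pupil_linearity_in_amplitude(self):
        quiet = dict(noise_sd=0, drift_sd=0, blink_rate_base=0, msacc_rate_base=0)
        sched = make_schedule(1)
        r1 = generate_eye_session(sched, [True], EyeDynamicsParams(**quiet), seed=9)
        r2 = generate_eye_session(
            sched, [True],
            EyeDynamicsParams(pupil_dilation_amp=80.0, **quiet), seed=9,
        )
        base = EyeDynamicsParams().pupil_baseline
        np.testing.assert_allclose(r2.pupil - base, 2 * (r1.pupil - base), atol=1e-9)


class TestEEG:
    def test_noiseless_no_report_has_van_not_p3(self):
        tpl = default_erp_templates(noise_sd=0.0)
        ep = noiseless_epoch(tpl, perceived=True, condition="no_report")
        means = erp.erp_window_means(ep, tpl.times)
        oz = tpl.channels.index("Oz")
        pz = tpl.channels.index("Pz")
        assert means["VAN"][oz] < -1.0  # VAN present (negative)
        assert abs(means["P3"][pz]) < 0.05  # P3 absent without report

    def test_noiseless_report_adds_late_components(self):
        tpl = default_erp_templates(noise_sd=0.0)
        ep = noiseless_epoch(tpl, perceived=True, condition="report")
        means = erp.erp_window_means(ep, tpl.times)
        pz = tpl.channels.index("Pz")
        assert means["P3"][pz] > 1.0

    def test_not_perceived_only_n100(self):
        tpl = default_erp_templates(noise_sd=0.0)
        ep = noiseless_epoch(tpl, perceived=False, condition="report")
        means = erp.erp_window_means(ep, tpl.times)
        oz = tpl.channels.index("Oz")
        assert means["N100"][oz] < -1.0
        assert abs(means["VAN"][oz]) < 0.3  # only the N100 tail leaks in
        assert abs(means["P3"][oz]) < 0.05

    def test_trial_average_noise_shrinks_as_sqrt_k(self):
        tpl = default_erp_templates(noise_sd=6.0)
        sets = generate_eeg_epochs(1, 64, tpl, "no_report", seed=10)
        es = sets[0]
        # component-free pre-stimulus samples
        pre = es.times < -0.1
        avg = es.epochs[:, :, es.perceived].mean(axis=2)
        resid_sd = avg[:, pre].std()
        expected = 6.0 / np.sqrt(64)
        assert resid_sd == pytest.approx(expected, rel=0.25)

    def test_amplitude_linearity(self):
        tpl = default_erp_templates(noise_sd=0.0)
        doubled = ErpTemplateSet(
            components=tuple(
                ErpComponent(c.name, c.polarity, c.peak_latency, c.width,
                             c.channel_weights, 2 * c.amplitude,
                             c.report_dependent, c.perception_dependent)
                for c in tpl.components
            ),
            noise_sd=0.0,
        )
        a = noiseless_epoch(tpl, True, "report")
        b = noiseless_epoch(doubled, True, "report")
        np.testing.assert_allclose(b, 2 * a, atol=1e-12)

    def test_empty_channel_weights_rejected(self):
        with pytest.raises(ValueError, match="channel_weights"):
            ErpTemplateSet(
                components=(
                    ErpComponent("VAN", -1, 0.2, 0.02, (), 5.0),
                ),
            )

    def test_tap_first_peak_latency(self):
        from noreport.synth import tap_template

        t = np.linspace(-0.2, 1.4, 1601)
        tap = tap_template(t)
        assert np.allclose(tap[t <= 0.25], 0.0)
        pk = peak_latency(tap, t, (0.25, 0.65), polarity=1)
        assert pk.latency == pytest.approx(0.43, abs=0.005)
        assert tap[t > 0.9].min() < 0  # biphasic


class TestFMRI:
    def test_report_run_volume_count(self):
        assert run_volume_count("report", "testing", tr=1.0) == 720
        assert run_volume_count("report_noreport", "testing", tr=1.0) == 700

    def test_noiseless_network_extrema_bins(self):
        tpl = BoldTemplateSet(noise_sd=0.0)
        sess = generate_fmri_session(2, 1, tpl, "report", seed=11,
                                     participant_scale_sd=0.0)
        masks = tpl.network_masks()
        t = tpl.times
        das_tc = sess.difference[0][masks["DAS"]][0]
        assert 3.0 <= t[np.argmax(das_tc)] <= 4.0
        dmn_tc = sess.difference[0][masks["DMN"]][0]
        assert 6.0 <= t[np.argmin(dmn_tc)] <= 8.0
        tpn_tc = sess.difference[0][masks["TPN"]][0]
        assert 5.0 <= t[np.argmax(tpn_tc)] <= 7.0

    def test_null_voxels_follow_t_distribution(self):
        tpl = BoldTemplateSet()
        n_part = 15
        sess = generate_fmri_session(n_part, 10, tpl, "report", seed=12)
        masks = tpl.network_masks()
        null = ~(masks["DAS"] | masks["TPN"] | masks["DMN"])
        x = sess.not_perceived.percent_change[:, null, :]
        tvals = stats.ttest_1samp(x, 0.0, axis=0).statistic.ravel()
        frac = np.mean(np.abs(tvals) > 2.0)
        expect = 2 * stats.t.sf(2.0, df=n_part - 1)
        se = np.sqrt(expect * (1 - expect) / tvals.size)
        # samples within a voxel are independent draws here, so the binomial
        # SE applies directly
        assert abs(frac - expect) < 3 * se + 0.002

    def test_template_amplitude_recovered_noiselessly(self):
        # das_peak on the TR grid so the template peak is sampled exactly
        tpl = BoldTemplateSet(noise_sd=0.0, das_amp=1.3, das_peak=3.0)
        sess = generate_fmri_session(1, 1, tpl, "report", seed=13,
                                     participant_scale_sd=0.0)
        das = tpl.network_masks()["DAS"]
        peak = sess.difference[0][das].max()
        assert peak == pytest.approx(1.3, abs=1e-9)

    def test_mask_outside_grid_rejected(self):
        tpl = BoldTemplateSet(grid_dims=(10, 10, 6))
        with pytest.raises(ValueError, match="outside grid"):
            tpl.network_masks()


class TestISISegments:
    def test_midpoint_center_time(self):
        sched = [
            pg.StimulusEvent(onset=10.0, location_set="quadrant", location=1,
                             opacity_condition="threshold", opacity=0.1),
            pg.StimulusEvent(onset=26.0, location_set="central", location=2,
                             opacity_condition="threshold", opacity=0.1),
        ]
        rec = generate_eye_session(sched, [False, False], seed=14, tail=12.0)
        segs = generate_isi_segments(sched, rec)
        assert len(segs) == 1
        assert segs[0][0] == pytest.approx(18.0)

    def test_short_isi_excluded(self):
        sched = make_schedule(3, start=10.0, spacing=10.0)  # 10 s < 12 s epoch
        rec = generate_eye_session(sched, [False] * 3, seed=15)
        assert generate_isi_segments(sched, rec) == []

    def test_injected_arousal_pupil_peak(self):
        params = EyeDynamicsParams(
            noise_sd=0, drift_sd=0, blink_rate_base=0, msacc_rate_base=0
        )
        sched = [
            pg.StimulusEvent(onset=10.0, location_set="quadrant", location=1,
                             opacity_condition="threshold", opacity=0.1),
            pg.StimulusEvent(onset=30.0, location_set="central", location=1,
                             opacity_condition="threshold", opacity=0.1),
        ]
        rec = generate_eye_session(sched, [False, False], params, seed=16, tail=12.0)
        center = 20.0
        segs = generate_isi_segments(
            sched, rec, arousal_events=[center], params=params, seed=17
        )
        (c, epoch), = segs
        peak_rel = epoch.times[np.argmax(epoch.pupil_corrected)]
        assert peak_rel == pytest.approx(params.pupil_peak_latency, abs=0.02)
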