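import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazesurprise.events import compute_kinematics, detect_saccades
from gazesurprise.simulate import (
    GeneratorConfig,
    SaccadeWaveform,
    _draw_anticipatory_onset,
    _solve_latency_location,
    draw_subject_effects,
    generate_memory_task,
    generate_session,
    generate_subject,
    generate_trial,
    inject_blinks,
    synthesize_pupil_trace,
    synthesize_saccade_waveform,
)
from gazesurprise.task import CONDITIONS, TrialSchedule


class TestWaveform:
    def test_duration_forced_by_raised_cosine_mean(self):
        # mean speed of a raised cosine is half the peak -> D = 2A/Vp
        wf = SaccadeWaveform(12.0, (1.0, 0.0), 350.0, start_ms=0.0)
        assert wf.duration_ms == pytest.approx(2 * 12.0 / 350.0 * 1000.0)

    def test_displacement_integrates_to_amplitude(self):
        wf = SaccadeWaveform(12.0, (1.0, 0.0), 350.0, start_ms=100.0)
        end = wf.displacement(np.array([1000.0]))[0]
        assert end[0] == pytest.approx(12.0, abs=1e-9)
        assert end[1] == 0.0

    def test_rightward_17deg_final_displacement(self):
        t, xy = synthesize_saccade_waveform(17.0, (1.0, 0.0), 400.0,
                                            onset_ms=0.0, sample_rate=500.0)
        assert xy[-1, 0] == pytest.approx(17.0, abs=1e-6)
        assert np.all(xy[:, 1] == 0.0)

    def test_sampled_peak_velocity_within_2pct(self):
        t, xy = synthesize_saccade_waveform(12.0, (1.0, 0.0), 350.0,
                                            onset_ms=0.0, sample_rate=500.0)
        v = np.diff(xy[:, 0]) / np.diff(t) * 1000.0
        assert abs(v.max() - 350.0) / 350.0 < 0.02

    def test_subthreshold_peak_velocity_refused(self):
        with pytest.raises(ValueError):
            SaccadeWaveform(1.0, (1.0, 0.0), 20.0, start_ms=0.0)
        with pytest.raises(ValueError):
            SaccadeWaveform(-1.0, (1.0, 0.0), 300.0, start_ms=0.0)

    def test_roundtrip_through_detector(self):
        # detection on the synthetic waveform recovers onset within 4 ms
        # and amplitude within 0.3 deg
        dt = 2.0
        t = np.arange(0, 1000, dt)
        wf = SaccadeWaveform(12.0, (1.0, 0.0), 350.0, start_ms=400.0)
        xy = wf.displacement(t)
        kin = compute_kinematics(t, xy[:, 0], xy[:, 1])
        sacc = detect_saccades(kin, xy[:, 0], xy[:, 1])
        assert len(sacc) == 1
        assert abs(sacc[0].onset_ms - wf.onset_ms) <= 4.0
        assert abs(sacc[0].amplitude - 12.0) <= 0.3


class TestTrialGeneration:
    def test_zero_anticipatory_rate_yields_one_visually_guided(self):
        cfg = GeneratorConfig(seed=0, anticipatory_rate_overall=0.0,
                              blink_rate=0.0)
        rng = np.random.default_rng(0)
        eff = draw_subject_effects(cfg, rng)
        for _ in range(10):
            tr = generate_trial(cfg, eff, CONDITIONS[2], rng)
            sacc = tr.ground_truth["saccades"]
            assert len(sacc) == 1
            assert sacc[0]["klass"] == "visually_guided"
            assert sacc[0]["latency_re_is"] >= 100.0

    def test_su1_anticipatory_injection_rate(self):
        # Monte-Carlo: injected fraction within 3 binomial SDs of the
        # SU1 per-condition rate derived from the pooled 5.5% and IRRs
        cfg = GeneratorConfig(seed=0, sample_rate=100.0, pupil_noise_sd=0.0,
                              gaze_noise_sd=0.0, gaze_jitter_sd=0.0,
                              blink_rate=0.0)
        p = cfg.anticipatory_rate_by_condition()[0]
        rng = np.random.default_rng(5)
        eff = draw_subject_effects(cfg, rng)
        n = 3000
        hits = sum(
            generate_trial(cfg, eff, CONDITIONS[0], rng)
            .ground_truth["saccades"][0]["klass"] == "anticipatory"
            for _ in range(n))
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sd

    def test_anticipatory_onset_mixture(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(1)
        draws = [_draw_anticipatory_onset(cfg, rng) for _ in range(6000)]
        early = np.array([t for m, t in draws if m == "early"])
        late = np.array([t for m, t in draws if m == "late"])
        w = len(early) / len(draws)
        assert abs(w - 32 / 182) < 3 * math.sqrt(w * (1 - w) / len(draws))
        assert early.min() >= 0.0 and early.max() < 500.0
        assert late.min() >= 1000.0 and late.max() <= 1900.0
        # late-mode density increases over the window
        counts, _ = np.histogram(late, bins=9, range=(1000.0, 1900.0))
        rho, _ = sps.spearmanr(np.arange(9), counts)
        assert rho > 0

    def test_anticipatory_amplitude_modes(self):
        # force anticipatory trials, check the two amplitude modes
        cfg = GeneratorConfig(seed=0, sample_rate=100.0,
                              anticipatory_rate_overall=0.5,
                              anticipatory_irr_by_condition=(1.0, 1.0, 1.0, 1.0),
                              pupil_noise_sd=0.0, gaze_noise_sd=0.0,
                              gaze_jitter_sd=0.0, blink_rate=0.0)
        rng = np.random.default_rng(8)
        eff = draw_subject_effects(cfg, rng)
        amp = {"early": [], "late": []}
        while len(amp["late"]) < 400:
            s = generate_trial(cfg, eff, CONDITIONS[0], rng).ground_truth[
                "saccades"][0]
            if s["klass"] == "anticipatory" and s["mode"] in amp:
                amp[s["mode"]].append(s["amplitude"])
        for mode, target in (("early", 11.7), ("late", 12.9)):
            m = np.asarray(amp[mode])
            assert abs(m.mean() - target) < 3 * m.std() / math.sqrt(len(m))

    def test_latency_truncation_correction(self):
        # marginal mean of truncated draws equals the configured mean
        cfg = GeneratorConfig()
        loc = _solve_latency_location(215.8, cfg.latency_subject_sd,
                                      cfg.latency_residual_sd, 100.0)
        assert loc < 215.8  # shifted down to offset truncation inflation
        rng = np.random.default_rng(2)
        n_subj, n_per = 400, 50
        means = []
        for _ in range(n_subj):
            b = rng.normal(0, cfg.latency_subject_sd)
            a = (100.0 - loc - b) / cfg.latency_residual_sd
            means.append(sps.truncnorm.rvs(
                a, np.inf, loc=loc + b, scale=cfg.latency_residual_sd,
                size=n_per, random_state=rng).mean())
        means = np.asarray(means)
        assert abs(means.mean() - 215.8) < 3 * means.std() / math.sqrt(n_subj)


class TestPupilTrace:
    def test_noiseless_plateau_equals_configured_effect(self):
        cfg = GeneratorConfig(pupil_noise_sd=0.0)
        sched = TrialSchedule.standard()
        t = np.arange(-500.0, sched.is_onset + 1200.0, 2.0)
        p = synthesize_pupil_trace(t, sched, effect_mm=0.24, baseline_mm=4.0,
                                   cfg=cfg, rng=np.random.default_rng(0))
        win = (t >= sched.ws_offset + 800.0) & (t < sched.is_onset)
        base = (t >= sched.ws_offset - 100.0) & (t < sched.ws_offset)
        assert p[win].mean() - p[base].mean() == pytest.approx(0.24, abs=1e-12)

    def test_effect_ramp_confined_to_foreperiod(self):
        cfg = GeneratorConfig(pupil_noise_sd=0.0)
        sched = TrialSchedule.standard()
        t = np.arange(-500.0, sched.is_onset, 2.0)
        p0 = synthesize_pupil_trace(t, sched, 0.0, 4.0, cfg,
                                    np.random.default_rng(0))
        p1 = synthesize_pupil_trace(t, sched, 0.24, 4.0, cfg,
                                    np.random.default_rng(0))
        diff = p1 - p0
        assert np.all(diff[t <= sched.ws_offset + 500.0] == 0.0)
        plateau = t >= sched.ws_offset + 800.0
        assert np.allclose(diff[plateau], 0.24)


class TestBlinks:
    def test_zero_rate_is_identity(self):
        cfg = GeneratorConfig(blink_rate=0.0)
        t = np.arange(0, 5000, 2.0)
        valid = np.ones(len(t), bool)
        blinks = inject_blinks(t, valid, cfg, np.random.default_rng(0))
        assert blinks == []
        assert valid.all()

    def test_poisson_count_over_long_span(self):
        cfg = GeneratorConfig(blink_rate=0.1)
        rng = np.random.default_rng(4)
        t = np.arange(0, 100_000.0, 2.0)   # 100 s
        total = 0
        for _ in range(10):                # 1000 s in total
            valid = np.ones(len(t), bool)
            total += len(inject_blinks(t, valid, cfg, rng))
        lam = 0.1 * 1000.0
        assert abs(total - lam) < 3 * math.sqrt(lam)

    def test_logged_blinks_cover_invalid_samples(self):
        cfg = GeneratorConfig(blink_rate=1.0)
        t = np.arange(0, 10_000.0, 2.0)
        valid = np.ones(len(t), bool)
        blinks = inject_blinks(t, valid, cfg, np.random.default_rng(1))
        assert blinks
        for start, end in blinks:
            inside = (t >= start) & (t <= end)
            assert not valid[inside].any()
        # validity flags only change inside logged spans
        outside = np.ones(len(t), bool)
        for start, end in blinks:
            outside &= ~((t >= start) & (t <= end))
        assert valid[outside].all()


class TestSession:
    def test_deterministic_under_fixed_seed(self):
        cfg = GeneratorConfig(seed=9, n_subjects=1, trials_per_condition=2)
        a = generate_session(cfg).subjects[0].samples_frame()
        b = generate_session(cfg).subjects[0].samples_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_distinct_seeds_give_distinct_traces(self):
        a = generate_subject(GeneratorConfig(seed=1, n_subjects=1,
                                             trials_per_condition=1), 0)
        b = generate_subject(GeneratorConfig(seed=2, n_subjects=1,
                                             trials_per_condition=1), 0)
        assert not np.array_equal(a.trials[0].x_deg, b.trials[0].x_deg)

    def test_balanced_conditions_and_trial_count(self, clean_subject,
                                                 clean_config):
        conds = [tr.condition.n_cued for tr in clean_subject.trials]
        assert len(conds) == 4 * clean_config.trials_per_condition
        for c in (1, 2, 3, 4):
            assert conds.count(c) == clean_config.trials_per_condition

    def test_events_inside_trial_span(self, clean_subject):
        for tr in clean_subject.trials:
            for s in tr.ground_truth["saccades"]:
                assert tr.t_ms[0] <= s["motion_start_ms"]
                assert s["offset_ms"] <= tr.t_ms[-1]

    def test_memory_task_shape_and_accuracy(self):
        cfg = GeneratorConfig(seed=3, n_subjects=30)
        mem = generate_memory_task(cfg)
        assert len(mem) == 30 * 4 * cfg.memory_trials_per_mi
        assert set(mem["mi"]) == {1, 2, 3, 4}
        # configured accuracies are typical-subject values; the marginal
        # accuracy is dragged down by the subject logit heterogeneity
        assert 0.85 <= mem["correct"].mean() <= 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(sample_rate=0.0)
    with pytest.raises(ValueError):
        GeneratorConfig(latency_mean_by_condition=(90.0, 233.5, 244.8, 247.8))
    with pytest.raises(ValueError):
        GeneratorConfig(anticipatory_irr_by_condition=(0.5, 0.3, 0.2, 0.2))
    with pytest.raises(ValueError):
        GeneratorConfig(gaze_noise_sd=-0.1)


def test_per_condition_rates_recover_pooled_rate():
    cfg = GeneratorConfig()
    rates = cfg.anticipatory_rate_by_condition()
    assert np.mean(rates) == pytest.approx(0.055)
    assert rates[0] / rates[1] == pytest.approx(3.91)
    assert rates[0] / rates[3] == pytest.approx(5.82)
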