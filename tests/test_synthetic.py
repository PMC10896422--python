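"""The synthetic study generator: EEG structure, artifacts, gait, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from dualtask_ef.features import band_power, psd_welch, relative_power
from dualtask_ef.gait import reference_curves
from dualtask_ef.synthetic import (EEGSimConfig, GaitSimConfig,
                                   inject_artifacts, headline_level_effects,
                                   simulate_eeg_recording, simulate_gait_trial,
                                   simulate_study)


class TestEEGSimulation:
    def test_sample_count(self):
        rec = simulate_eeg_recording(EEGSimConfig(), 1, 300.0, seed=0)
        assert rec.data.shape == (8, 153_600)

    def test_deterministic_per_seed(self, fast_eeg_cfg):
        a = simulate_eeg_recording(fast_eeg_cfg, 2, 5.0, seed=9)
        b = simulate_eeg_recording(fast_eeg_cfg, 2, 5.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_flat_level_effects_equal_power_in_expectation(self):
        """With unit factors, level 1 vs level 3 delta power differ only by noise."""
        cfg = EEGSimConfig(sampling_rate=128.0)
        p1, p3 = [], []
        for seed in range(20):
            for level, out in ((1, p1), (3, p3)):
                rec = simulate_eeg_recording(cfg, level, 20.0, seed=seed + 100 * level)
                spec = psd_welch(rec.data, rec.sfreq)
                out.append(band_power(spec, "delta").mean())
        assert sps.ttest_ind(p1, p3).pvalue > 0.01

    def test_injected_delta_trend_monotone_in_most_seeds(self):
        cfg = EEGSimConfig(sampling_rate=128.0,
                           level_effects={("Fz", "delta", "relative"):
                                          (1.0, 1.3, 1.6)})
        wins = 0
        for seed in range(50):
            vals = []
            for level in (1, 2, 3):
                rec = simulate_eeg_recording(cfg, level, 20.0,
                                             seed=1000 * seed + level)
                spec = psd_welch(rec.data, rec.sfreq)
                vals.append(relative_power(spec, "delta")[rec.channel_index("Fz")])
            wins += vals[0] < vals[1] < vals[2]
        assert wins >= 45

    def test_band_component_parseval(self):
        """Each band component contributes its configured variance (5%, 60 s)."""
        cfg = EEGSimConfig(sampling_rate=256.0, background_scale=0.0,
                           band_amplitudes={"alpha": 3.0})
        rec = simulate_eeg_recording(cfg, 1, 60.0, seed=5)
        var = rec.data[0].var()
        assert var == pytest.approx(9.0, rel=0.05)
        spec = psd_welch(rec.data[:1], 256.0, segment_s=4.0)
        assert band_power(spec, (6.0, 15.0))[0] == pytest.approx(9.0, rel=0.10)

    def test_walking_setting_boosts_background(self, fast_eeg_cfg):
        sit = simulate_eeg_recording(fast_eeg_cfg, 1, 20.0, seed=6,
                                     setting="sitting")
        walk = simulate_eeg_recording(fast_eeg_cfg, 1, 20.0, seed=6,
                                      setting="walking")
        assert walk.data.std() > 1.5 * sit.data.std()


class TestArtifacts:
    def test_zero_rate_is_noop(self, fast_eeg_cfg):
        cfg = EEGSimConfig(sampling_rate=128.0, artifact_rate=0.0)
        rec = simulate_eeg_recording(cfg, 1, 10.0, seed=1)
        out, intervals = inject_artifacts(rec, cfg, seed=2)
        assert intervals == []
        assert np.array_equal(out.data, rec.data)

    def test_burst_count_follows_poisson_law(self):
        """Aggregate count over 20 seeds within the Poisson 99% interval."""
        cfg = EEGSimConfig(sampling_rate=128.0, artifact_rate=4.0)
        rec = simulate_eeg_recording(cfg, 1, 300.0, seed=3)
        total = sum(len(inject_artifacts(rec, cfg, seed=s)[1])
                    for s in range(20))
        lam = 20 * 4.0 * 300.0 / 60.0     # 400 expected
        lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
        assert lo <= total <= hi

    def test_burst_amplitude_dominates_background(self):
        cfg = EEGSimConfig(sampling_rate=128.0, artifact_rate=6.0,
                           artifact_amplitude=20.0)
        rec = simulate_eeg_recording(cfg, 1, 60.0, seed=4)
        out, intervals = inject_artifacts(rec, cfg, seed=5)
        assert intervals
        mask = np.zeros(rec.n_samples, bool)
        for t0, t1 in intervals:
            mask[int(t0 * rec.sfreq):int(t1 * rec.sfreq)] = True
        rms_in = np.sqrt(np.mean(out.data[:, mask] ** 2, axis=1)).max()
        rms_out = np.sqrt(np.mean(out.data[:, ~mask] ** 2, axis=1)).mean()
        assert rms_in >= 10.0 * rms_out


class TestGaitSimulation:
    def test_noise_free_curves_equal_reference(self):
        cfg = GaitSimConfig(curve_noise_sd=0.0, stride_noise_sd=0.0)
        trial = simulate_gait_trial(cfg, "baseline", seed=0)
        ref = reference_curves()
        for side in ("left", "right"):
            assert np.allclose(trial.curves[side].to_numpy(), ref.to_numpy())

    def test_invalid_condition_raises(self):
        with pytest.raises(ValueError):
            simulate_gait_trial(GaitSimConfig(), "jumping", seed=0)

    def test_inconsistent_double_support_rejected(self):
        with pytest.raises(ValueError):
            GaitSimConfig(stance_fraction=0.62, double_support_fraction=0.4)


class TestStudy:
    @pytest.fixture
    def tiny_kwargs(self):
        return dict(n_subjects=3, go_trials=6, nback_trials=5,
                    baseline_duration=8.0)

    def test_same_master_seed_identical(self, tiny_kwargs):
        cfg = EEGSimConfig(sampling_rate=128.0)
        a = simulate_study(cfg, GaitSimConfig(), master_seed=5,
                           settings=("sitting",), **tiny_kwargs)
        b = simulate_study(cfg, GaitSimConfig(), master_seed=5,
                           settings=("sitting",), **tiny_kwargs)
        for key in a.eeg:
            assert np.array_equal(a.eeg[key].data, b.eeg[key].data)
        assert a.responses == b.responses

    def test_recording_count(self, tiny_kwargs):
        study = simulate_study(EEGSimConfig(sampling_rate=128.0),
                               GaitSimConfig(), master_seed=1, **tiny_kwargs)
        # n_subjects x 2 settings x 5 conditions
        assert len(study.eeg) == 3 * 2 * 5
        assert len(study.gait) == 3 * 5

    def test_recordings_span_their_schedules(self, tiny_kwargs):
        study = simulate_study(EEGSimConfig(sampling_rate=128.0),
                               GaitSimConfig(), master_seed=2,
                               settings=("sitting",), **tiny_kwargs)
        for cond, sched in study.schedules.items():
            spec = study.task_specs[cond]
            dur = spec.n_trials * (spec.inter_trial_interval
                                   if spec.task_name == "go_nogo"
                                   else spec.trial_duration)
            rec = study.eeg[(1, "sitting", cond)]
            assert rec.duration == pytest.approx(dur, abs=1.0 / rec.sfreq)
            assert sched.onsets[-1] < rec.duration

    def test_default_ground_truth_headline_effects(self):
        effects = headline_level_effects()
        study = simulate_study(
            EEGSimConfig(sampling_rate=128.0, level_effects=effects),
            GaitSimConfig(), master_seed=3, n_subjects=3,
            settings=("sitting",), go_trials=6, nback_trials=5,
            baseline_duration=8.0)
        gt = {(g["channel"], g["band"], g["power_type"], g["direction"])
              for g in study.ground_truth}
        assert ("Fz", "delta", "relative", "+") in gt
        assert ("Fz", "high_beta", "absolute", "-") in gt
        assert len(gt) == len(effects)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            simulate_study(EEGSimConfig(sampling_rate=128.0), GaitSimConfig(),
                           n_subjects=2)
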