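import numpy as np
import pytest

from seizure_advisory.synth import (
    AedCoupling,
    DiaryLog,
    InfeasibleRateError,
    SimulationConfig,
    aed_level_at,
    simulate_aed_levels,
    simulate_diary,
    simulate_record,
    simulate_seizure_times,
    simulate_signals,
    write_edf,
)

MONTH = 30 * 86400.0


def small_config(**kw):
    defaults = dict(duration=10 * 86400.0, seizure_rate=4.0,
                    sampling_rate=0.2, n_channels=2,
                    signature_band=(0.015, 0.035), feature_epoch=240.0,
                    seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSeizureTimes:
    def test_zero_rate_gives_empty(self):
        ev = simulate_seizure_times(small_config(seizure_rate=0.0))
        assert ev.size == 0

    def test_refractory_gaps(self):
        cfg = small_config(duration=90 * 86400.0, seizure_rate=4.0, seed=7)
        ev = simulate_seizure_times(cfg)
        assert np.all(np.diff(ev) >= cfg.refractory)
        assert np.all((ev >= 0) & (ev < cfg.duration))

    def test_infeasible_rate(self):
        # 8-h refractory allows at most 90 events / 30 days
        with pytest.raises(InfeasibleRateError):
            simulate_seizure_times(small_config(seizure_rate=95.0))

    def test_monte_carlo_monthly_mean(self):
        # dead-time-corrected intensity: long-run rate should be ~4/month
        cfg = small_config(duration=10000 * MONTH, seizure_rate=4.0, seed=1)
        ev = simulate_seizure_times(cfg)
        months = cfg.duration / MONTH
        mean = len(ev) / months
        se = np.sqrt(len(ev)) / months
        assert abs(mean - 4.0) <= 3 * se

    def test_deterministic(self):
        cfg = small_config(seed=5)
        a = simulate_seizure_times(cfg)
        b = simulate_seizure_times(cfg)
        np.testing.assert_array_equal(a, b)


class TestAedLevels:
    def test_half_life(self):
        # single dose: one half-life later the level halves
        cfg = small_config(aed_dose_interval=1e12, aed_halflife=12 * 3600.0)
        t = np.array([0.0, 12 * 3600.0])
        lv = aed_level_at(cfg, t)
        assert lv[1] == pytest.approx(lv[0] / 2)

    def test_sawtooth_when_interval_much_longer(self):
        cfg = small_config(aed_halflife=3600.0, aed_dose_interval=24 * 3600.0)
        trough = aed_level_at(cfg, np.array([24 * 3600.0 - 1.0]))[0]
        peak = aed_level_at(cfg, np.array([0.0]))[0]
        assert trough < 0.01 * peak

    def test_accumulation_plateau(self):
        # interval << half-life: geometric series -> dose / (1 - r)
        cfg = small_config(aed_halflife=100 * 3600.0, aed_dose_interval=3600.0)
        lam = np.log(2) / cfg.aed_halflife
        r = np.exp(-lam * cfg.aed_dose_interval)
        t = np.array([2000 * 3600.0])
        assert aed_level_at(cfg, t)[0] == pytest.approx(1.0 / (1 - r), rel=0.01)

    def test_strictly_positive(self):
        _, lv = simulate_aed_levels(small_config(), sample_interval=3600.0)
        assert np.all(lv > 0)


class TestSignals:
    def test_no_events_stationary(self):
        cfg = small_config(effect_size=2.0)
        x = simulate_signals(np.empty(0), cfg)
        assert x.shape == (cfg.n_channels, cfg.n_samples)
        thirds = np.array_split(x[0], 3)
        v = [t.var() for t in thirds]
        assert max(v) / min(v) < 1.5

    def test_planted_feature_mean_shift(self):
        # pre-ictal mean of the in-band feature exceeds the interictal mean
        from seizure_advisory.synth import _band_component, _epoch_mean_abs

        cfg = small_config(duration=30 * 86400.0, seizure_rate=8.0,
                           effect_size=2.0, seed=2)
        ev = simulate_seizure_times(cfg)
        assert len(ev) >= 4
        x = simulate_signals(ev, cfg)
        band = _band_component(x[0], cfg.sampling_rate, cfg.signature_band)
        spe = int(round(cfg.feature_epoch * cfg.sampling_rate))
        feat = _epoch_mean_abs(band, spe)
        starts = np.arange(len(feat)) * cfg.feature_epoch
        ends = starts + cfg.feature_epoch
        pre = np.zeros(len(feat), bool)
        near = np.zeros(len(feat), bool)
        for t in ev:
            pre |= (starts < t) & (ends > t - cfg.preictal_horizon)
            near |= (starts < t + 2 * cfg.ictal_duration) & (ends > t)
        inter = ~pre & ~near
        assert feat[pre & ~near].mean() > feat[inter].mean()

    def test_null_effect_indistinguishable(self):
        # effect_size=0: pre-ictal vs interictal two-sample test rejects at
        # ~nominal rate over seeds
        from scipy.stats import mannwhitneyu

        from seizure_advisory.synth import _band_component, _epoch_mean_abs

        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = small_config(duration=20 * 86400.0, seizure_rate=8.0,
                               effect_size=0.0, seed=seed)
            ev = simulate_seizure_times(cfg)
            if len(ev) < 2:
                n_seeds -= 1
                continue
            x = simulate_signals(ev, cfg)
            band = _band_component(x[0], cfg.sampling_rate, cfg.signature_band)
            spe = int(round(cfg.feature_epoch * cfg.sampling_rate))
            feat = _epoch_mean_abs(band, spe)
            starts = np.arange(len(feat)) * cfg.feature_epoch
            ends = starts + cfg.feature_epoch
            pre = np.zeros(len(feat), bool)
            near = np.zeros(len(feat), bool)
            for t in ev:
                pre |= (starts < t) & (ends > t - cfg.preictal_horizon)
                near |= (starts < t + 2 * cfg.ictal_duration) & (ends > t)
            p = mannwhitneyu(feat[pre & ~near], feat[~pre & ~near]).pvalue
            rejections += p < 0.05
        assert rejections <= 4  # ~1 expected at alpha=0.05 over ~20 seeds

    def test_event_outside_duration_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            simulate_signals(np.array([cfg.duration + 1.0]), cfg)

    def test_aed_coupling_changes_signal(self):
        cfg = small_config()
        coupled = cfg.replace(aed_coupling=(
            AedCoupling(channel=0, band=(0.015, 0.035), coefficient=2.0),))
        x0 = simulate_signals(np.empty(0), cfg)
        x1 = simulate_signals(np.empty(0), coupled)
        assert not np.allclose(x0[0], x1[0])
        np.testing.assert_allclose(x0[1], x1[1])  # uncoupled channel intact


class TestDiary:
    def test_perfect_diary(self):
        cfg = small_config(diary_report_prob=1.0, diary_false_rate=0.0)
        ev = np.array([10.0, 500.0, 9000.0])
        diary = simulate_diary(ev, cfg)
        np.testing.assert_array_equal(diary.times, ev)
        assert diary.is_true_report.all()

    def test_binomial_reporting(self):
        cfg = small_config(duration=3650 * 86400.0, diary_report_prob=0.5,
                           diary_false_rate=0.0, seed=3)
        ev = np.arange(2000) * (cfg.duration / 2000.0)
        diary = simulate_diary(ev, cfg)
        ratio = len(diary.times) / len(ev)
        assert abs(ratio - 0.5) < 3 * np.sqrt(0.25 / len(ev))

    def test_ratio_spans_published_range(self):
        # low reporting + false entries can push the diary/true monthly ratio
        # below 0.1 or above 13 depending on the true rate
        cfg = small_config(duration=12 * MONTH, seizure_rate=0.0,
                           diary_report_prob=0.37, diary_false_rate=5.0,
                           seed=4)
        sparse_true = np.array([MONTH])  # ~0.083/month true rate
        d = simulate_diary(sparse_true, cfg)
        months = cfg.duration / MONTH
        ratio_high = (len(d.times) / months) / (len(sparse_true) / months)
        assert ratio_high > 13

        cfg2 = cfg.replace(diary_false_rate=0.0, diary_report_prob=0.05,
                           seed=5)
        dense_true = np.arange(0, cfg2.duration, 2 * 86400.0)
        d2 = simulate_diary(dense_true, cfg2)
        ratio_low = len(d2.times) / len(dense_true)
        assert ratio_low < 0.1

    def test_unsorted_diary_rejected(self):
        with pytest.raises(ValueError):
            DiaryLog(times=np.array([5.0, 1.0]),
                     is_true_report=np.array([True, True]))


class TestRecordAndConfig:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig.desk_scale(seed=11, effect_size=2.0)
        a = simulate_record(cfg)
        b = simulate_record(cfg)
        np.testing.assert_array_equal(a.signals, b.signals)
        np.testing.assert_array_equal(a.true_events, b.true_events)
        np.testing.assert_array_equal(a.diary.times, b.diary.times)

    def test_signal_shape_invariant(self):
        cfg = small_config()
        rec = simulate_record(cfg)
        assert rec.signals.shape == (cfg.n_channels,
                                     int(round(cfg.duration
                                               * cfg.sampling_rate)))
        assert np.all(np.diff(rec.true_events) >= cfg.refractory)

    def test_config_json_round_trip(self):
        cfg = small_config(aed_coupling=(
            AedCoupling(channel=1, band=(0.01, 0.02), coefficient=0.5),))
        assert SimulationConfig.from_json(cfg.to_json()) == cfg

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            small_config(duration=-1.0)
        with pytest.raises(ValueError):
            small_config(preictal_horizon=9 * 3600.0)  # >= refractory
        with pytest.raises(ValueError):
            small_config(signature_band=(0.05, 0.2))   # above Nyquist
        with pytest.raises(ValueError):
            small_config(diary_report_prob=1.5)


class TestEdfWriter:
    def test_round_trip_against_mne(self, tmp_path):
        mne = pytest.importorskip("mne")

        rng = np.random.default_rng(0)
        fs = 0.2
        x = rng.standard_normal((3, int(fs * 36000)))
        path = tmp_path / "sig.edf"
        write_edf(path, x, fs)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        assert raw.info["sfreq"] == pytest.approx(fs)
        got = raw.get_data() * 1e6     # MNE returns volts; we wrote uV
        assert got.shape[0] == 3
        n = min(got.shape[1], x.shape[1])
        # 16-bit quantization: amplitudes recovered to ~1e-3 of the range
        scale = np.ptp(x) / 65535
        assert np.max(np.abs(got[:, :n] - x[:, :n])) < 4 * scale
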