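"""Properties of the synthetic cohort generator."""

import numpy as np
import pytest

import whisklearn as wl
from whisklearn import behavior, synthetic
from whisklearn.data_model import ValidationError
from whisklearn.synthetic import (SEPKernel, evoked_kernel, simulate_behavior,
                                  simulate_lfp, simulate_spikes, _rng)


class TestScenario:
    def test_validation_catches_bad_fields(self):
        with pytest.raises(ValidationError):
            wl.detection_scenario(n_days=0)
        with pytest.raises(ValidationError):
            wl.detection_scenario(
                learning=synthetic.LearningCurve(hit_asymptote=0.1,
                                                 fa_rate=0.2))
        sc = wl.detection_scenario()
        sc.spikes.frac_positive = 0.8
        sc.spikes.frac_negative = 0.8
        with pytest.raises(ValidationError):
            sc.validate()

    def test_yaml_round_trip(self, tmp_path, small_scenario):
        p = tmp_path / "sc.yaml"
        synthetic.save_scenario(small_scenario, p)
        sc2 = synthetic.load_scenario(p)
        assert sc2 == small_scenario


class TestBehaviorSimulation:
    def test_same_seed_identical(self, small_scenario):
        s1 = simulate_behavior(small_scenario)
        s2 = simulate_behavior(small_scenario)
        for (m1, t1), (m2, t2) in zip(s1, s2):
            assert m1 == m2
            assert np.array_equal(t1.onset_s, t2.onset_s)
            assert list(t1.outcome) == list(t2.outcome)

    def test_schedule_and_outcome_invariants(self, small_scenario):
        for _, t in simulate_behavior(small_scenario):
            t.validate()
            d = np.diff(t.onset_s)
            assert d.min() >= 6.0 and d.max() <= 12.0

    def test_learning_increases_dprime(self):
        sc = wl.detection_scenario(n_mice=14, n_days=8,
                                   trials_per_session=120, seed=21)
        sessions = simulate_behavior(sc)
        d1, dlast = [], []
        for meta, t in sessions:
            p = behavior.session_performance(t, meta.day_index)
            if meta.day_index == 1:
                d1.append(p.dprime)
            elif meta.day_index == sc.n_days:
                dlast.append(p.dprime)
        assert np.mean(dlast) > np.mean(d1) + 1.0

    def test_neutral_licks_independent_of_stimulus(self):
        sc = wl.neutral_scenario(n_mice=6, n_days=2, trials_per_session=150,
                                 seed=5)
        n_stim = n_hit = n_catch = n_fa = 0
        for _, t in simulate_behavior(sc):
            p = behavior.session_performance(t)
            n_stim += p.n_stim; n_hit += p.n_hit
            n_catch += p.n_catch; n_fa += p.n_fa
        hr, fr = n_hit / n_stim, n_fa / n_catch
        # stimulus-conditioned lick probability equals the unconditional
        # one: difference within ~3 binomial SEs
        se = np.sqrt(hr * (1 - hr) / n_stim + fr * (1 - fr) / n_catch)
        assert abs(hr - fr) < 3 * se

    def test_opto_light_fraction(self):
        sc = wl.opto_scenario(n_mice=2, trials_per_session=500, seed=2)
        meta, t = simulate_behavior(sc)[0]
        frac = t.light_on.mean()
        assert abs(frac - 0.30) < 3 * np.sqrt(0.3 * 0.7 / len(t))


class TestLFPSimulation:
    def test_noise_free_sep_equals_kernel(self):
        sc = wl.detection_scenario(n_mice=1, n_days=1, trials_per_session=20,
                                   noise=synthetic.NoiseSpec(std_uv=0.0, session_gain_sd=0.0),
                                   seed=4)
        meta, t = simulate_behavior(sc)[0]
        rec = simulate_lfp(t, sc, 0.0, np.random.default_rng(0))
        k = evoked_kernel(sc.kernel["wS1"], sc.fs_hz)
        ch = rec.channel_of("wS1")
        stim = np.flatnonzero((t.kind == "stimulus") & (t.outcome == "miss"))
        assert len(stim) > 0
        s0 = int(round(t.onset_s[stim[0]] * sc.fs_hz))
        seg = rec.samples[ch, s0 + 4:s0 + len(k)].astype(float)  # skip artifact
        expected = sc.coupling["wS1"].base_uv * k[4:]
        assert np.allclose(seg, expected, atol=0.5)

    def test_amplitude_coupling_by_construction(self):
        sc = wl.detection_scenario(n_mice=1, n_days=1, trials_per_session=20,
                                   noise=synthetic.NoiseSpec(std_uv=0.0, session_gain_sd=0.0),
                                   seed=4)
        meta, t = simulate_behavior(sc)[0]
        miss = np.flatnonzero((t.kind == "stimulus") & (t.outcome == "miss"))
        s0 = int(round(t.onset_s[miss[0]] * sc.fs_hz))
        pk = s0 + int(round(sc.kernel["mPFC"].peak_ms * 2))
        ch = 5  # mPFC
        a0 = simulate_lfp(t, sc, 0.0, np.random.default_rng(0)).samples[ch, pk]
        a2 = simulate_lfp(t, sc, 2.0, np.random.default_rng(0)).samples[ch, pk]
        assert a2 - a0 == pytest.approx(
            2.0 * sc.coupling["mPFC"].dprime_gain_uv, rel=1e-3)

    def test_programmed_latency_ordering(self):
        sc = wl.detection_scenario()
        assert sc.kernel["wS1"].latency_ms < sc.kernel["dCA1"].latency_ms
        assert sc.kernel["wS1"].latency_ms < sc.kernel["mPFC"].latency_ms
        # kernels realize the configured latency: first nonzero sample
        for area in ("wS1", "mPFC"):
            k = evoked_kernel(sc.kernel[area], sc.fs_hz)
            first = np.flatnonzero(np.abs(k) > 1e-12)[0] / sc.fs_hz * 1e3
            assert first == pytest.approx(sc.kernel[area].latency_ms, abs=1.0)

    def test_kernel_peaks_at_configured_time(self):
        k = SEPKernel(10.0, 30.0, -1, 25.0)
        y = evoked_kernel(k, 2000.0)
        t_pk = np.argmax(np.abs(y)) / 2.0  # ms
        assert t_pk == pytest.approx(30.0, abs=0.5)
        assert y[int(t_pk * 2)] < 0  # polarity applied

    def test_ar1_autocorrelation(self):
        sc = wl.detection_scenario(n_mice=1, n_days=1, trials_per_session=5,
                                   seed=9)
        # pure-noise channel: zero coupling scenario
        for a in sc.coupling.values():
            a.base_uv = a.dprime_gain_uv = a.hit_gain = 0.0
        sc.trials_per_session = 2
        meta, t = simulate_behavior(sc)[0]
        # measure on a long pre-stimulus stretch, clear of the injected
        # 1 ms stimulus artifacts
        t.onset_s = t.onset_s + 120.0
        rec = simulate_lfp(t, sc, 0.0, np.random.default_rng(1))
        x = rec.samples[0, :200_000].astype(float)
        x = x - x.mean()
        rho = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert rho == pytest.approx(sc.noise.ar1, abs=0.01)
        assert x.std() == pytest.approx(sc.noise.std_uv, rel=0.1)


class TestSpikeSimulation:
    def test_zero_depth_no_modulation(self):
        sc = wl.detection_scenario(n_mice=1, n_days=1, trials_per_session=100,
                                   seed=6)
        sc.spikes.modulation_depth = 0.0
        sc.spikes.n_units = 20
        meta, t = simulate_behavior(sc)[0]
        units = simulate_spikes(t, sc, np.random.default_rng(2))
        from whisklearn.spikes import trial_window_counts
        stim = t.onset_s[(t.kind == "stimulus") & (t.outcome != "aborted")]
        pre = np.mean([trial_window_counts(u, stim, (-1, 0)).mean()
                       for u in units])
        post = np.mean([trial_window_counts(u, stim, (0, 1)).mean()
                        for u in units])
        assert post == pytest.approx(pre, rel=0.1)

    def test_positive_units_increase_rate(self):
        sc = wl.detection_scenario(n_mice=1, n_days=8, trials_per_session=200,
                                   seed=8)
        sc.spikes.frac_positive, sc.spikes.frac_negative = 1.0, 0.0
        sc.spikes.modulation_depth = 1.0  # 2x post rate
        sc.spikes.n_units = 40
        rng = _rng(sc, "behavior", 0, 8)
        t = synthetic._simulate_detection_session(sc, rng, day=8)
        units = simulate_spikes(t, sc, np.random.default_rng(3))
        from whisklearn.spikes import trial_window_counts
        hits = t.onset_s[t.outcome == "hit"]
        n_up = sum(trial_window_counts(u, hits, (0, 1)).mean()
                   > trial_window_counts(u, hits, (-1, 0)).mean()
                   for u in units)
        assert n_up >= 0.95 * len(units)

    def test_waveform_duration_bimodal(self):
        sc = wl.detection_scenario(n_mice=1, n_days=1, trials_per_session=30,
                                   seed=2)
        sc.spikes.n_units = 300
        meta, t = simulate_behavior(sc)[0]
        units = simulate_spikes(t, sc, np.random.default_rng(4))
        durs = np.array([u.trough_to_peak_ms for u in units])
        fsu = durs < 0.35
        assert durs[fsu].mean() == pytest.approx(sc.spikes.fsu_duration_ms,
                                                 abs=0.03)
        assert durs[~fsu].mean() == pytest.approx(sc.spikes.rsu_duration_ms,
                                                  abs=0.03)
        assert 0.1 < fsu.mean() < 0.3


class TestMakeCohort:
    def test_file_count_and_manifest(self, tmp_path):
        sc = wl.detection_scenario(n_mice=2, n_days=3, trials_per_session=12,
                                   seed=13)
        sc.spikes.n_units = 4
        paths = synthetic.make_cohort(sc, tmp_path / "c")
        assert len(paths) == 6
        import pandas as pd
        man = pd.read_csv(tmp_path / "c" / "manifest.csv")
        assert len(man) == 6
        assert set(man.columns) >= {"mouse", "day", "paradigm", "seed"}

    def test_same_seed_byte_identical_csvs(self, tmp_path):
        sc = wl.detection_scenario(n_mice=1, n_days=2, trials_per_session=10,
                                   seed=17)
        sc.spikes.n_units = 2
        synthetic.make_cohort(sc, tmp_path / "a")
        synthetic.make_cohort(sc, tmp_path / "b")
        fa = (tmp_path / "a" / "mouse00_day01.trials.csv").read_bytes()
        fb = (tmp_path / "b" / "mouse00_day01.trials.csv").read_bytes()
        assert fa == fb

    def test_zero_days_errors(self, tmp_path):
        with pytest.raises(ValidationError):
            wl.detection_scenario(n_days=0)
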