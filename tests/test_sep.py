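"""Evoked-potential preprocessing, measurement and statistics."""

import numpy as np
import pytest

from whisklearn import sep, synthetic
from whisklearn.data_model import ContinuousRecording, TrialTable
from whisklearn.sep import (SEPResult, average_sep, extract_epochs,
                            find_first_peak, measure_at, onset_latency,
                            peak_vs_dprime_correlation, preprocess_lfp,
                            windowed_paired_test)

FS = 2000.0


def _rec(x):
    return ContinuousRecording(np.atleast_2d(x), fs_hz=FS,
                               channel_area={0: "wS1"})


def _trials(onsets):
    n = len(onsets)
    return TrialTable(np.arange(n), np.array(["stimulus"] * n, object),
                      np.asarray(onsets, float), [np.zeros(0)] * n,
                      np.array(["miss"] * n, object), np.zeros(n, bool),
                      np.zeros(n, bool), np.full(n, np.nan))


class TestPreprocess:
    def test_200hz_attenuated_20db(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 200.0 * t)
        y = preprocess_lfp(_rec(x), []).samples[0]
        # project onto the 200 Hz quadrature pair away from the filter
        # edge transients
        mid = slice(int(5 * FS), int(15 * FS))
        c = np.cos(2 * np.pi * 200.0 * t[mid])
        s = np.sin(2 * np.pi * 200.0 * t[mid])
        amp = 2 * np.hypot(np.mean(y[mid] * c), np.mean(y[mid] * s))
        assert amp < 0.1  # >= 20 dB below the unit input

    def test_dc_removed(self):
        x = np.full(int(30 * FS), 123.0)
        y = preprocess_lfp(_rec(x), []).samples[0]
        assert abs(np.mean(y[int(5 * FS):int(25 * FS)])) < 1e-3

    def test_passband_preserved(self):
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = preprocess_lfp(_rec(x), []).samples[0]
        mid = slice(int(10 * FS), int(30 * FS))
        assert np.std(y[mid]) == pytest.approx(np.std(x[mid]), rel=0.02)

    def test_artifact_blanked(self):
        x = np.zeros(int(20 * FS))
        s0 = int(10 * FS)
        x[s0:s0 + 2] = 4000.0  # 1 ms artifact
        y = preprocess_lfp(_rec(x), [10.0]).samples[0]
        assert np.abs(y[s0 - 2:s0 + 6]).max() < 5.0

    def test_stim_outside_recording_errors(self):
        with pytest.raises(ValueError):
            preprocess_lfp(_rec(np.zeros(1000)), [5.0])

    def test_low_fs_rejected(self):
        r = ContinuousRecording(np.zeros((1, 100)), fs_hz=100.0,
                                channel_area={0: "wS1"})
        with pytest.raises(ValueError):
            preprocess_lfp(r, [])


class TestEpochs:
    def test_baseline_zero_and_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(100 * FS))
        trials = _trials([10.0, 20.0, 30.0])
        ep = extract_epochs(_rec(x), trials, "wS1")
        assert ep.data.shape[0] == 3
        base = ep.data[:, ep.time_s < 0]
        assert np.abs(base.mean(axis=1)).max() < 1e-9

    def test_constant_signal_all_zero(self):
        trials = _trials([10.0])
        ep = extract_epochs(_rec(np.full(int(20 * FS), 55.0)), trials, "wS1")
        assert np.abs(ep.data).max() < 1e-12

    def test_out_of_bounds_trial_dropped_with_warning(self):
        trials = _trials([10.0, 19.95])
        with pytest.warns(UserWarning, match="dropped"):
            ep = extract_epochs(_rec(np.zeros(int(20 * FS))), trials, "wS1")
        assert ep.data.shape[0] == 1


class TestAverage:
    def test_identical_epochs_mean_is_epoch(self):
        ep = sep.EpochArray(np.tile(np.arange(10.0), (4, 1)),
                            np.arange(10) / FS, "wS1", np.arange(4))
        res = average_sep(ep)
        assert np.allclose(res.waveform, np.arange(10.0))

    def test_sem_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        t = np.arange(50) / FS
        sems = []
        for n in (50, 200):
            ep = sep.EpochArray(rng.standard_normal((n, 50)), t, "wS1",
                                np.arange(n))
            sems.append(average_sep(ep).sem.mean())
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.15)

    def test_empty_mask_errors(self):
        ep = sep.EpochArray(np.zeros((3, 5)), np.arange(5) / FS, "wS1",
                            np.arange(3))
        with pytest.raises(ValueError):
            average_sep(ep, np.zeros(3, bool))


def _sep_from(y, fs=FS, t0=-0.05):
    t = t0 + np.arange(len(y)) / fs
    return SEPResult(waveform=np.asarray(y, float), sem=np.zeros(len(y)),
                     time_s=t, n_trials=10)


def _bump(center_ms, amp, width_ms=8.0, dur_ms=350.0, noise_sd=1.0, seed=0):
    """Band-limited bump fixture: noise smoothed as a filtered SEP is."""
    t = -50.0 + np.arange(int(dur_ms * FS / 1e3)) / FS * 1e3
    rng = np.random.default_rng(seed)
    y = amp * np.exp(-0.5 * ((t - center_ms) / width_ms) ** 2)
    noise = np.convolve(rng.standard_normal(len(t) + 8), np.ones(9) / 9.0,
                        mode="valid") * noise_sd * 3.0
    return _sep_from(y + noise)


class TestPeakMeasures:
    def test_single_negative_bump(self):
        s = _bump(30.0, -200.0)
        pt, pa = find_first_peak(s, polarity=-1)
        assert pt == pytest.approx(0.030, abs=0.002)
        assert pa == pytest.approx(-200.0, rel=0.05)

    def test_first_of_two_bumps(self):
        s = _bump(20.0, -100.0)
        s2 = _bump(60.0, -150.0, noise_sd=0.0)
        s.waveform += s2.waveform
        pt, _ = find_first_peak(s, polarity=-1)
        assert pt == pytest.approx(0.020, abs=0.003)

    def test_flat_waveform_no_peak(self):
        s = _sep_from(np.zeros(700))
        pt, pa = find_first_peak(s, polarity=-1)
        assert pt is None and pa is None

    def test_measure_at_peak_and_flat(self):
        s = _bump(30.0, -200.0, noise_sd=0.0)
        assert measure_at(s, 0.030) == pytest.approx(-200.0, rel=1e-6)
        assert measure_at(s, -0.04) == pytest.approx(0.0, abs=1e-6)

    def test_measure_at_nearest_sample(self):
        y = np.arange(10.0)
        s = SEPResult(y, np.zeros(10), np.arange(10) / FS, 1)
        # 1.6 sample periods -> nearest is sample 2
        assert measure_at(s, 1.6 / FS) == 2.0

    def test_measure_at_out_of_range(self):
        s = _bump(30.0, -200.0)
        with pytest.raises(ValueError):
            measure_at(s, 1.0)

    def test_onset_latency_step(self):
        rng = np.random.default_rng(2)
        t = -50.0 + np.arange(700) / 2.0
        y = rng.standard_normal(700)
        y[t >= 8.0] += 10.0 * y.std()
        assert onset_latency(_sep_from(y)) == pytest.approx(0.008, abs=0.002)

    def test_onset_latency_precedes_peak(self, trained_session):
        sc, trials, perf, lfp = trained_session
        stim = (trials.kind == "stimulus") & (trials.outcome != "aborted")
        rec = preprocess_lfp(lfp, trials.onset_s[stim])
        ep = extract_epochs(rec, trials.select(stim), "wS1")
        s = average_sep(ep)
        lat = onset_latency(s)
        pt, _ = find_first_peak(s, -1)
        assert lat is not None and pt is not None and lat <= pt

    def test_pure_noise_rarely_crosses(self):
        # independent-sample noise: a 5 ms (10-sample) run above 2 SD
        # essentially never happens
        hits = 0
        for seed in range(40):
            y = np.random.default_rng(seed).standard_normal(700)
            if onset_latency(_sep_from(y)) is not None:
                hits += 1
        assert hits <= 2  # >= 95% of seeds report no onset


class TestWindowedTest:
    def test_equal_conditions_p_one(self):
        t = np.arange(-100, 600) / FS
        w = np.random.default_rng(0).standard_normal(len(t))
        pairs = [(w, w.copy()) for _ in range(8)]
        _, p = windowed_paired_test(pairs, t)
        assert np.all(p == 1.0)

    def test_localized_shift_detected(self):
        rng = np.random.default_rng(1)
        t = -0.05 + np.arange(700) / FS
        pairs = []
        for _ in range(10):
            a = rng.standard_normal(700)
            b = a + rng.standard_normal(700) * 0.2
            b[(t >= 0.020) & (t < 0.040)] += 3.0
            pairs.append((a, b))
        centers, p = windowed_paired_test(pairs, t)
        inside = (centers >= 0.020) & (centers < 0.040)
        assert np.all(p[inside] < 0.05)
        assert np.mean(p[~inside] < 0.05) < 0.25

    def test_single_mouse_errors(self):
        t = np.arange(100) / FS
        with pytest.raises(ValueError):
            windowed_paired_test([(np.zeros(100), np.zeros(100))], t)


class TestCorrelation:
    def test_perfect_linear(self):
        r, p, n = peak_vs_dprime_correlation([2, 4, 6, 8], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_hand_computed_half(self):
        r, _, _ = peak_vs_dprime_correlation([1, 3, 2], [1, 2, 3])
        assert r == pytest.approx(0.5)

    def test_null_r_small(self):
        rng = np.random.default_rng(4)
        r, p, _ = peak_vs_dprime_correlation(rng.standard_normal(500),
                                             rng.standard_normal(500))
        assert abs(r) < 0.12

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            peak_vs_dprime_correlation([1, 1, 1], [1, 2, 3])


class TestPipelineProperties:
    def test_linearity_in_input_scale(self, trained_session):
        sc, trials, perf, lfp = trained_session
        stim_mask = (trials.kind == "stimulus") & (trials.outcome != "aborted")
        stim = trials.onset_s[stim_mask]
        sub = trials.select(np.flatnonzero(stim_mask)[:40])
        rec1 = preprocess_lfp(lfp, stim)
        scaled = ContinuousRecording(lfp.samples[:1] * 3.0, lfp.fs_hz,
                                     {0: "wS1"}, lfp.t0_s)
        rec3 = preprocess_lfp(scaled, stim)
        s1 = average_sep(extract_epochs(rec1, sub, "wS1"))
        s3 = average_sep(extract_epochs(rec3, sub, "wS1"))
        assert np.allclose(s3.waveform, 3.0 * s1.waveform, rtol=1e-3,
                           atol=0.5)
        p1 = find_first_peak(s1, -1)[0]
        p3 = find_first_peak(s3, -1)[0]
        assert p1 == p3

    def test_parameter_recovery_trained_session(self, trained_session):
        # peak time within 2 ms, amplitude within 10%, latency close to
        # the programmed kernel on a realistic-noise 200-trial session
        sc, trials, perf, lfp = trained_session
        stim_mask = (trials.kind == "stimulus") & (trials.outcome != "aborted")
        rec = preprocess_lfp(lfp, trials.onset_s[stim_mask])
        for area in ("wS1", "dCA1", "mPFC"):
            ep = extract_epochs(rec, trials, area)
            rows = np.isin(ep.trial_ids, trials.trial_id[
                stim_mask & (trials.outcome == "hit") & ~trials.premature])
            s = average_sep(ep, rows)
            pt, pa = find_first_peak(s, sep.AREA_POLARITY[area])
            k, c = sc.kernel[area], sc.coupling[area]
            prog = (c.base_uv + c.dprime_gain_uv * perf.dprime) \
                * (1 + c.hit_gain) * k.polarity
            assert pt * 1e3 == pytest.approx(k.peak_ms, abs=2.0)
            assert pa == pytest.approx(prog, rel=0.10)
            lat = onset_latency(s)
            assert lat is not None and lat * 1e3 == pytest.approx(
                k.latency_ms, abs=3.0)


class TestLatencyOrdering:
    def test_programmed_ordering_detected(self):
        rng = np.random.default_rng(6)
        lat = {"wS1": rng.normal(8, 1, 10), "dCA1": rng.normal(18, 1.5, 10),
               "mPFC": rng.normal(22, 2, 10)}
        res = sep.latency_ordering_test(lat)
        assert res.pair("wS1", "mPFC")

    def test_identical_distributions_rarely_flag(self):
        rng = np.random.default_rng(7)
        n_any = 0
        for _ in range(50):
            lat = {a: rng.normal(10, 2, 8) for a in ("wS1", "dCA1", "mPFC")}
            n_any += sep.latency_ordering_test(lat).significant.any()
        assert n_any / 50 <= 0.10
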