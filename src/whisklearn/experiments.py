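"""Cohort-level experiment runners.

These functions chain the synthetic generator and the analysis stages
into the study's standard designs: a detection-task learning cohort
(day-by-day performance, D1-vs-Trained evoked contrasts, peak-vs-d'
correlations, latency ordering, Stimulus-Probability decoding, spike
modulation), a neutral-exposure control cohort, and the optogenetic
and muscimol inactivation designs.  Everything is computed in memory,
one session at a time; the returned tables are the tabular equivalents
of the study figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, inactivation, roc, sep, spikes, stats, synthetic
from .behavior import session_performance, select_exposed_sessions, select_trained_sessions
from .synthetic import CohortScenario, _rng

__all__ = [
    "CohortResults", "analyze_learning_cohort", "analyze_opto_cohort",
    "analyze_muscimol_cohort", "analyze_spike_cohort",
]


@dataclass
class CohortResults:
    """Analysis products of one learning (or exposure) cohort.

    Keys of per-mouse dicts are mouse ids; waveform dicts are keyed by
    (mouse, area).  ``peak_table`` holds one row per (mouse, day, area)
    with the session d' and the SEP amplitude at the reference peak
    time; ``reference_days`` are the trained (or exposed) day indices
    per mouse.
    """

    scenario: CohortScenario
    perf_table: pd.DataFrame
    reference_days: dict
    time_s: np.ndarray = None
    peak_table: pd.DataFrame = None
    peak_time: dict = field(default_factory=dict)
    d1_waves: dict = field(default_factory=dict)
    ref_waves: dict = field(default_factory=dict)
    hit_waves: dict = field(default_factory=dict)
    miss_waves: dict = field(default_factory=dict)
    latencies: dict = field(default_factory=dict)
    peak_times_by_area: dict = field(default_factory=dict)
    sp_by_area: dict = field(default_factory=dict)

    def d1_vs_ref_windowed(self, area: str):
        """5 ms-window Wilcoxon map of D1 vs reference-condition SEPs."""
        pairs = [(self.d1_waves[(m, area)], self.ref_waves[(m, area)])
                 for m in self.reference_days
                 if (m, area) in self.d1_waves and (m, area) in self.ref_waves]
        return sep.windowed_paired_test(pairs, self.time_s)

    def d1_vs_ref_peak_test(self, area: str):
        """Peak-amplitude comparison D1 vs reference condition.

        Amplitudes are measured at the per-mouse reference peak time.
        Returns (per-mouse D1 amps, reference amps, two-sided p).
        """
        d1, ref = [], []
        for m in self.reference_days:
            key = (m, area)
            if key not in self.peak_time or self.peak_time[key] is None:
                continue
            t_ref = self.peak_time[key]
            w = self.time_s
            i = int(np.argmin(np.abs(w - t_ref)))
            d1.append(self.d1_waves[key][i])
            ref.append(self.ref_waves[key][i])
        d1, ref = np.asarray(d1), np.asarray(ref)
        return d1, ref, stats.wilcoxon_signed_rank(d1, ref)

    def peak_dprime_correlation(self, area: str):
        """Pearson r (with t-based p) of SEP amplitude vs d' pooled
        over (mouse, day)."""
        sub = self.peak_table[self.peak_table.area == area]
        return sep.peak_vs_dprime_correlation(sub.peak_amp.values,
                                              sub.dprime.values)


def _session_waves(scenario, trials, perf, areas, lfp_rng, sp_seed=None):
    """Simulate + preprocess one session's LFP and return per-area
    all-stimulus / hit / miss waveforms (and optional SP curve data)."""
    rec = synthetic.simulate_lfp(trials, scenario, perf.dprime, lfp_rng,
                                 areas=areas)
    stim_mask_tbl = (trials.kind == "stimulus") & (trials.outcome != "aborted")
    rec = sep.preprocess_lfp(rec, trials.onset_s[stim_mask_tbl])
    out = {}
    for area in areas:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep = sep.extract_epochs(rec, trials, area)
        by_id = {tid: i for i, tid in enumerate(trials.trial_id)}
        rows = np.array([by_id[t] for t in ep.trial_ids])
        keep = trials.outcome[rows] != "aborted"
        kind = trials.kind[rows]
        outcome = trials.outcome[rows]
        premature = trials.premature[rows]
        stim_rows = keep & (kind == "stimulus")
        all_sep = sep.average_sep(ep, stim_rows)
        res = {"time_s": ep.time_s, "all_stim": all_sep.waveform,
               "all_sem": all_sep.sem}
        hit_rows = stim_rows & (outcome == "hit") & ~premature
        miss_rows = stim_rows & (outcome == "miss")
        res["hit"] = (sep.average_sep(ep, hit_rows).waveform
                      if hit_rows.any() else None)
        res["n_hit"] = int(hit_rows.sum())
        res["miss"] = (sep.average_sep(ep, miss_rows).waveform
                       if miss_rows.any() else None)
        res["n_miss"] = int(miss_rows.sum())
        if sp_seed is not None:
            ep_keep = sep.EpochArray(ep.data[keep], ep.time_s, area,
                                     ep.trial_ids[keep])
            res["sp"] = roc.sp_curve(ep_keep, (kind == "stimulus")[keep],
                                     seed=sp_seed,
                                     polarity=sep.AREA_POLARITY[area])
        out[area] = res
    return out


def analyze_learning_cohort(scenario: CohortScenario, areas=None,
                            lfp_days: str = "all",
                            with_sp: bool = True) -> CohortResults:
    """Full behavioral + SEP (+ SP) analysis of a detection or
    neutral-exposure cohort.

    ``lfp_days`` is ``"all"`` (every day enters the peak-vs-d'
    table) or ``"contrast"`` (only day 1 and the reference days are
    simulated and analyzed — sufficient for the D1-vs-reference and SP
    analyses).  The reference condition is the first three trained
    days (day > 4, d' > 1) for the detection paradigm, or the last
    three exposure days for neutral exposure.
    """
    scenario.validate()
    areas = list(scenario.areas if areas is None else areas)
    neutral = scenario.paradigm == "neutral_exposure"
    sessions = synthetic.simulate_behavior(scenario)

    by_mouse = {}
    for meta, trials in sessions:
        by_mouse.setdefault(meta.mouse_id, []).append((meta, trials))

    perf_rows, ref_days = {}, {}
    results = CohortResults(scenario=scenario, perf_table=None,
                            reference_days={})
    peak_rows = []
    for mouse, sess in by_mouse.items():
        sess.sort(key=lambda mt: mt[0].day_index)
        perfs = [session_performance(t, day_index=m.day_index)
                 for m, t in sess]
        perf_rows[mouse] = perfs
        if neutral:
            days = select_exposed_sessions(scenario.n_days)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                days = select_trained_sessions(perfs)
        ref_days[mouse] = days
        lfp_day_set = (set(d for d in range(1, scenario.n_days + 1))
                       if lfp_days == "all" else set([1]) | set(days))

        day_waves = {}
        sp_accum = {a: [] for a in areas}
        for (meta, trials), perf in zip(sess, perfs):
            d = meta.day_index
            if d not in lfp_day_set:
                continue
            want_sp = with_sp and d in days
            mouse_num = int("".join(c for c in mouse if c.isdigit()) or 0)
            waves = _session_waves(
                scenario, trials, perf, areas,
                _rng(scenario, "lfp", mouse_num, d),
                sp_seed=(scenario.seed * 1009 + mouse_num * 131 + d) % (2**31)
                if want_sp else None)
            day_waves[d] = waves
            results.time_s = waves[areas[0]]["time_s"]
            if want_sp:
                for a in areas:
                    sp_accum[a].append(waves[a]["sp"])

        for a in areas:
            ref_wave = np.mean([day_waves[d][a]["all_stim"] for d in days],
                               axis=0) if days else None
            if ref_wave is None:
                continue
            # averaging k session means shrinks the noise by sqrt(k)
            ref_sem = np.mean([day_waves[d][a]["all_sem"] for d in days],
                              axis=0) / np.sqrt(len(days))
            # The peak time is determined on the equal-per-session
            # pooled average of all analyzed sessions (D1 plus the
            # reference days): every session's noise then has the same
            # covariance with the selection statistic, so measuring the
            # conditions at the selected time carries no differential
            # noise-selection bias into the paired contrasts.
            if 1 in day_waves and 1 not in days:
                pool = [1] + list(days)
                peak_wave = np.mean([day_waves[d][a]["all_stim"]
                                     for d in pool], axis=0)
                peak_sem = (np.mean([day_waves[d][a]["all_sem"]
                                     for d in pool], axis=0)
                            / np.sqrt(len(pool)))
            else:
                peak_wave, peak_sem = ref_wave, ref_sem
            peak_sep = sep.SEPResult(waveform=peak_wave, sem=peak_sem,
                                     time_s=results.time_s,
                                     n_trials=len(days), area=a)
            ref_sep = sep.SEPResult(waveform=ref_wave, sem=ref_sem,
                                    time_s=results.time_s,
                                    n_trials=len(days), area=a)
            pk_t, _ = sep.find_first_peak(peak_sep, sep.AREA_POLARITY[a])
            results.peak_time[(mouse, a)] = pk_t
            results.ref_waves[(mouse, a)] = ref_wave
            if 1 in day_waves:
                results.d1_waves[(mouse, a)] = day_waves[1][a]["all_stim"]
            hits = [day_waves[d][a]["hit"] for d in days
                    if day_waves[d][a]["hit"] is not None]
            if hits:
                results.hit_waves[(mouse, a)] = np.mean(hits, axis=0)
            misses = [day_waves[d][a]["miss"] for d in days
                      if day_waves[d][a]["miss"] is not None]
            if misses:
                results.miss_waves[(mouse, a)] = np.mean(misses, axis=0)
            lat = sep.onset_latency(ref_sep)
            if lat is not None:
                results.latencies.setdefault(a, []).append(lat)
            if pk_t is not None:
                results.peak_times_by_area.setdefault(a, []).append(pk_t)
                i_pk = int(np.argmin(np.abs(results.time_s - pk_t)))
                pol = sep.AREA_POLARITY[a]
                for d, waves in day_waves.items():
                    perf_d = next(p for p in perfs if p.day_index == d)
                    # response magnitude: signed value rectified by the
                    # area's evoked polarity, so growth is positive
                    peak_rows.append({
                        "mouse": mouse, "day": d, "area": a,
                        "dprime": perf_d.dprime,
                        "peak_amp": pol * float(waves[a]["all_stim"][i_pk])})
            if with_sp and sp_accum[a]:
                _, m_sp, _ = roc.grand_average_sp(sp_accum[a])
                sh_m = np.mean([c.shuffle_mean for c in sp_accum[a]], axis=0)
                sh_s = np.mean([c.shuffle_sd for c in sp_accum[a]], axis=0)
                results.sp_by_area.setdefault(a, []).append(
                    roc.SPCurve(time_s=sp_accum[a][0].time_s, sp=m_sp,
                                shuffle_mean=sh_m, shuffle_sd=sh_s,
                                n_stim=sum(c.n_stim for c in sp_accum[a]),
                                n_catch=sum(c.n_catch for c in sp_accum[a]),
                                area=a))

    results.perf_table = behavior.performance_table(perf_rows)
    results.reference_days = ref_days
    results.peak_table = pd.DataFrame(peak_rows)
    return results


def analyze_spike_cohort(scenario: CohortScenario, n_mice: int = 7,
                         alpha: float = 0.05):
    """Spike modulation analysis on one trained session per mouse.

    Returns (population summary dict, list of ModulationResult, list
    of (delta_hz, significant) hit-miss outcomes).
    """
    scenario.validate()
    mod_results, hm_results = [], []
    for m in range(n_mice):
        rng_b = _rng(scenario, "behavior", m, scenario.n_days)
        trials = synthetic._simulate_detection_session(
            scenario, rng_b, day=scenario.n_days)
        trials = behavior.classify_trials(trials)
        units = synthetic.simulate_spikes(
            trials, scenario, _rng(scenario, "spikes", m, scenario.n_days))
        hit_mask = (trials.outcome == "hit") & ~trials.premature
        miss_mask = trials.outcome == "miss"
        hit_on = trials.onset_s[hit_mask]
        miss_on = trials.onset_s[miss_mask]
        for ui, u in enumerate(units):
            if spikes.classify_unit(u.trough_to_peak_ms) != "RSU":
                continue
            seed = (scenario.seed * 7919 + m * 211 + ui) % (2**31)
            mod = spikes.modulation_test(u, hit_on, seed=seed, alpha=alpha)
            mod_results.append(mod)
            if len(hit_on) >= 5 and len(miss_on) >= 5:
                delta, sig = spikes.hit_miss_unit_test(
                    u, hit_on, miss_on, seed=seed)
                hm_results.append({"unit_id": u.unit_id, "klass": mod.klass,
                                   "delta_hz": delta, "significant": sig})
    return spikes.population_summary(mod_results), mod_results, hm_results


def analyze_opto_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Light-on vs light-off hit/FA comparison per inactivated area.

    Returns one row per area with per-mouse mean rates and paired
    Wilcoxon p-values.
    """
    scenario.validate()
    sessions = synthetic.simulate_behavior(scenario)
    per_area = {}
    for meta, trials in sessions:
        on_p = session_performance(trials, light="on")
        off_p = session_performance(trials, light="off")
        per_area.setdefault(meta.target_area, []).append((on_p, off_p))
    rows = []
    for area, pairs in per_area.items():
        hit_on = [p[0].hit_rate for p in pairs]
        hit_off = [p[1].hit_rate for p in pairs]
        fa_on = [p[0].fa_rate for p in pairs]
        fa_off = [p[1].fa_rate for p in pairs]
        p_hit, p_fa = inactivation.opto_compare(hit_on, hit_off, fa_on, fa_off)
        rows.append({"area": area, "n_mice": len(pairs),
                     "hit_on": np.mean(hit_on), "hit_off": np.mean(hit_off),
                     "fa_on": np.mean(fa_on), "fa_off": np.mean(fa_off),
                     "p_hit": p_hit, "p_fa": p_fa})
    return pd.DataFrame(rows)


def analyze_muscimol_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Muscimol-vs-Ringer hit-rate comparison per area, Holm-adjusted.

    Rates are scored in the 5 min block starting 30 min post injection.
    """
    scenario.validate()
    sessions = synthetic.simulate_behavior(scenario)
    treated, control = {}, []
    for meta, trials in sessions:
        block = inactivation.extract_muscimol_block(trials)
        perf = session_performance(block)
        if meta.manipulation == "muscimol":
            treated.setdefault(meta.target_area, []).append(perf.hit_rate)
        else:
            control.append(perf.hit_rate)
    pvals = inactivation.muscimol_compare(treated, control)
    rows = [{"area": a, "n_treated": len(treated[a]),
             "n_control": len(control),
             "hit_treated": float(np.mean(treated[a])),
             "hit_control": float(np.mean(control)),
             "p_raw": pvals[a][0], "p_adj": pvals[a][1]}
            for a in treated]
    return pd.DataFrame(rows)
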