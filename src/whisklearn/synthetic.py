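"""Synthetic cohort generator for the whisker detection-task analyses.

Generates per-mouse, per-day sessions (trial tables, multi-channel LFP,
spike trains) with the statistical structure the downstream analyses
assume:

* go/no-go trial schedules with 6–12 s inter-trial intervals, 50%
  randomly interleaved catch trials, a 1 s response window, premature
  (<100 ms) licks, and no-lick-window aborts;
* day-by-day learning expressed as a logistic hit-rate curve at
  constant false-alarm rate;
* area-specific sensory-evoked LFP kernels (difference of
  exponentials) with onset latencies below 50 ms, ordered from sensory
  to frontal areas, whose amplitude in the learning-coupled areas
  (dCA1, mPFC) scales with the session's d' and is larger on hit than
  miss trials; additive AR(1) Gaussian noise and a 1 ms stimulus
  artifact at onset;
* spike populations with configurable fractions of positively and
  negatively modulated units (inhomogeneous Poisson, 1 s post-onset
  modulation, deeper on hits than misses) and a bimodal RSU/FSU
  trough-to-peak duration mixture;
* optogenetic (30% light trials) and muscimol/Ringer manipulations
  modeled as per-area multiplicative effects on the hit probability.

All randomness flows from a single master seed through fixed per-mouse,
per-day, per-signal substreams, so cohorts are bit-reproducible and the
outputs are independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .data_model import (AREAS, ContinuousRecording, SessionMeta, TrialTable,
                         UnitData, ValidationError, write_session)
from .behavior import classify_trials, session_performance

__all__ = [
    "AreaCoupling", "SEPKernel", "LearningCurve", "NoiseSpec", "SpikeSpec",
    "CohortScenario", "detection_scenario", "neutral_scenario",
    "opto_scenario", "muscimol_scenario", "load_scenario", "save_scenario",
    "simulate_behavior", "simulate_lfp", "simulate_spikes", "make_cohort",
    "evoked_kernel",
]


# ---------------------------------------------------------------------------
# Scenario definition
# ---------------------------------------------------------------------------

@dataclass
class AreaCoupling:
    """Evoked-amplitude model for one area: peak amplitude (µV) is
    ``base_uv + dprime_gain_uv * d'``, scaled by ``1 + hit_gain`` on
    hit trials."""

    base_uv: float
    dprime_gain_uv: float = 0.0
    hit_gain: float = 0.0


@dataclass
class SEPKernel:
    """Evoked-potential kernel shape for one area.

    Difference of exponentials starting at ``latency_ms`` and peaking
    at ``peak_ms`` (unit peak magnitude, signed by ``polarity``); the
    decay time constant is ``tau_decay_ms`` and the rise constant is
    solved from the requested peak time.
    """

    latency_ms: float
    peak_ms: float
    polarity: int = -1
    tau_decay_ms: float = 20.0


@dataclass
class LearningCurve:
    """Logistic day-by-day hit-rate curve at constant FA rate."""

    day_half: float = 3.5
    slope_days: float = 1.0
    hit_asymptote: float = 0.80
    fa_rate: float = 0.16

    def hit_prob(self, day: float) -> float:
        s = 1.0 / (1.0 + np.exp(-(day - self.day_half) / self.slope_days))
        return self.fa_rate + (self.hit_asymptote - self.fa_rate) * s


@dataclass
class NoiseSpec:
    """Additive LFP noise and session-level amplitude variability.

    ``std_uv`` is the marginal std of the AR(1) noise process;
    ``session_gain_sd`` is the log-scale SD of a lognormal gain applied
    to all evoked amplitudes of a session, emulating the day-to-day
    variability of evoked responses in chronic recordings.
    """

    std_uv: float = 40.0
    ar1: float = 0.98
    session_gain_sd: float = 0.05


@dataclass
class SpikeSpec:
    n_units: int = 60
    frac_positive: float = 1 / 3
    frac_negative: float = 1 / 3
    baseline_hz: float = 5.0
    modulation_depth: float = 0.5
    miss_depth_fraction: float = 0.4
    rsu_duration_ms: float = 0.60
    fsu_duration_ms: float = 0.25
    duration_sd_ms: float = 0.05
    fsu_fraction: float = 0.2


def _default_kernels() -> dict:
    # Latency/peak ordering follows the sensory-to-frontal recruitment
    # sequence, all latencies < 50 ms; mPFC polarity is positive.
    return {
        "wS1":  SEPKernel(8.0, 20.0, -1, 15.0),
        "wS2":  SEPKernel(10.0, 24.0, -1, 18.0),
        "wM1":  SEPKernel(12.0, 28.0, -1, 20.0),
        "PtA":  SEPKernel(14.0, 32.0, -1, 22.0),
        "dCA1": SEPKernel(18.0, 38.0, -1, 25.0),
        "mPFC": SEPKernel(22.0, 45.0, +1, 30.0),
    }


def _default_coupling() -> dict:
    # Sensory areas respond from day 1 and are d'-independent; the
    # learning-coupled areas start near zero and grow with d'.  The
    # early wS1 response carries no hit-vs-miss difference.
    return {
        "wS1":  AreaCoupling(300.0, 0.0, 0.0),
        "wS2":  AreaCoupling(250.0, 0.0, 0.10),
        "wM1":  AreaCoupling(120.0, 15.0, 0.20),
        "PtA":  AreaCoupling(140.0, 15.0, 0.20),
        "dCA1": AreaCoupling(30.0, 60.0, 0.30),
        "mPFC": AreaCoupling(20.0, 50.0, 0.30),
    }


@dataclass
class CohortScenario:
    """Complete description of a synthetic cohort."""

    paradigm: str = "detection"
    n_mice: int = 14
    n_days: int = 8
    trials_per_session: int = 200
    learning: LearningCurve = field(default_factory=LearningCurve)
    coupling: dict = field(default_factory=_default_coupling)
    kernel: dict = field(default_factory=_default_kernels)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    spikes: SpikeSpec = field(default_factory=SpikeSpec)
    seed: int = 0
    fs_hz: float = 2000.0
    catch_prob: float = 0.5
    abort_rate: float = 0.08
    premature_frac: float = 0.05
    neutral_lick_hz: float = 0.22
    light_fraction: float = 0.30
    opto_hit_effect: dict = field(default_factory=dict)
    opto_fa_effect: dict = field(default_factory=dict)
    muscimol_hit_effect: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_mice < 1:
            raise ValidationError("n_mice: must be >= 1")
        if self.n_days < 1:
            raise ValidationError("n_days: must be >= 1")
        if self.trials_per_session < 1:
            raise ValidationError("trials_per_session: must be >= 1")
        if not 0.0 < self.catch_prob < 1.0:
            raise ValidationError("catch_prob: must lie in (0, 1)")
        lc = self.learning
        if not (lc.fa_rate < lc.hit_asymptote <= 1.0):
            raise ValidationError(
                "learning: asymptotic hit rate must lie in (fa_rate, 1]")
        for area, k in self.kernel.items():
            if not k.latency_ms < k.peak_ms:
                raise ValidationError(f"kernel[{area}]: latency must precede peak")
            if not k.peak_ms - k.latency_ms < k.tau_decay_ms:
                raise ValidationError(
                    f"kernel[{area}]: peak_ms - latency_ms must be < tau_decay_ms")
        sp = self.spikes
        if not (0 <= sp.frac_positive <= 1 and 0 <= sp.frac_negative <= 1
                and sp.frac_positive + sp.frac_negative <= 1):
            raise ValidationError("spikes: modulated fractions must lie in [0,1] "
                                  "and sum to <= 1")
        if not 0 <= self.light_fraction <= 1:
            raise ValidationError("light_fraction: must lie in [0, 1]")
        if not -1 < self.noise.ar1 < 1:
            raise ValidationError("noise: AR(1) coefficient must lie in (-1, 1)")

    @property
    def areas(self) -> list:
        return [a for a in AREAS if a in self.kernel]


def detection_scenario(**overrides) -> CohortScenario:
    """Standard detection-task learning cohort (14 mice, 8 days)."""
    sc = CohortScenario(paradigm="detection", **overrides)
    sc.validate()
    return sc


def neutral_scenario(**overrides) -> CohortScenario:
    """Neutral-exposure cohort: same stimulus statistics, no
    stimulus-reward contingency, no learning-coupled evoked growth."""
    coupling = {
        "wS1":  AreaCoupling(300.0, 0.0, 0.0),
        "wS2":  AreaCoupling(250.0, 0.0, 0.0),
        "wM1":  AreaCoupling(120.0, 0.0, 0.0),
        "PtA":  AreaCoupling(140.0, 0.0, 0.0),
        "dCA1": AreaCoupling(10.0, 0.0, 0.0),
        "mPFC": AreaCoupling(5.0, 0.0, 0.0),
    }
    overrides.setdefault("coupling", coupling)
    overrides.setdefault("n_mice", 12)
    sc = CohortScenario(paradigm="neutral_exposure", **overrides)
    sc.validate()
    return sc


def opto_scenario(**overrides) -> CohortScenario:
    """Optogenetic inactivation in trained mice: light on 30% of
    trials; per-area multiplicative hit-probability effects."""
    overrides.setdefault("opto_hit_effect", {
        "wS1": 0.30, "wS2": 0.40, "wM1": 1.0,
        "PtA": 1.0, "dCA1": 0.35, "mPFC": 0.30})
    overrides.setdefault("n_mice", 8)
    sc = CohortScenario(paradigm="detection", **overrides)
    sc.validate()
    return sc


def muscimol_scenario(**overrides) -> CohortScenario:
    """Muscimol inactivation sessions (whole-session effect; the
    analysis scores a 5 min block starting 30 min post injection)."""
    overrides.setdefault("muscimol_hit_effect", {
        "wS1": 0.30, "wS2": 0.40, "wM1": 1.0,
        "PtA": 1.0, "dCA1": 0.35, "mPFC": 0.30})
    overrides.setdefault("trials_per_session", 260)
    overrides.setdefault("n_mice", 6)
    sc = CohortScenario(paradigm="detection", **overrides)
    sc.validate()
    return sc


# -- YAML round trip --------------------------------------------------------

def save_scenario(scenario: CohortScenario, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(scenario), f, sort_keys=False)


def load_scenario(path) -> CohortScenario:
    with open(path) as f:
        d = yaml.safe_load(f)
    d["learning"] = LearningCurve(**d["learning"])
    d["noise"] = NoiseSpec(**d["noise"])
    d["spikes"] = SpikeSpec(**d["spikes"])
    d["coupling"] = {a: AreaCoupling(**c) for a, c in d["coupling"].items()}
    d["kernel"] = {a: SEPKernel(**k) for a, k in d["kernel"].items()}
    sc = CohortScenario(**d)
    sc.validate()
    return sc


# ---------------------------------------------------------------------------
# Substream seeding
# ---------------------------------------------------------------------------

_STREAMS = {"behavior": 1, "lfp": 2, "spikes": 3}


def _rng(scenario: CohortScenario, stream: str, *key) -> np.random.Generator:
    """Per-(stream, mouse, day, ...) generator derived from the master
    seed by fixed offsets; independent of generation order."""
    return np.random.default_rng(
        [int(scenario.seed) & 0x7FFFFFFF, _STREAMS[stream], *map(int, key)])


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _lick_bout(rng, first: float, until: float = 1.8) -> np.ndarray:
    """A licking bout: first lick plus ~7 Hz follow-up licks."""
    licks = [first]
    t = first
    while True:
        t += rng.exponential(0.14)
        if t > until:
            break
        licks.append(t)
    return np.asarray(licks)


def _first_lick_latency(rng, premature_frac: float) -> float:
    if rng.random() < premature_frac:
        return float(rng.uniform(0.02, 0.099))
    # reaction-time-like latency, resampled into the response window
    for _ in range(100):
        lat = 0.12 + rng.exponential(0.22)
        if lat < 0.98:
            return float(lat)
    return 0.5


def _simulate_detection_session(scenario: CohortScenario, rng,
                                hit_mult_light: float = 1.0,
                                fa_mult_light: float = 1.0,
                                hit_mult_all: float = 1.0,
                                day: int = 1,
                                with_light: bool = False) -> TrialTable:
    lc = scenario.learning
    p_hit = min(1.0, lc.hit_prob(day) * hit_mult_all)
    p_fa = lc.fa_rate
    n = scenario.trials_per_session
    onset = 0.0
    rows = {k: [] for k in ("kind", "onset", "licks", "outcome",
                            "premature", "light", "reward")}
    for i in range(n):
        onset += rng.uniform(6.0, 12.0)
        kind = "stimulus" if rng.random() >= scenario.catch_prob else "catch"
        light = bool(with_light and rng.random() < scenario.light_fraction)
        ph = p_hit * (hit_mult_light if light else 1.0)
        pf = min(1.0, p_fa * (fa_mult_light if light else 1.0))
        if rng.random() < scenario.abort_rate:
            licks = np.array([rng.uniform(-4.0, -3.0)])
            rows["kind"].append(kind); rows["onset"].append(onset)
            rows["licks"].append(licks); rows["outcome"].append("aborted")
            rows["premature"].append(False); rows["light"].append(light)
            rows["reward"].append(np.nan)
            continue
        p_lick = ph if kind == "stimulus" else pf
        if rng.random() < p_lick:
            first = _first_lick_latency(rng, scenario.premature_frac)
            licks = _lick_bout(rng, first)
            outcome = "hit" if kind == "stimulus" else "false_alarm"
            reward = first if outcome == "hit" else np.nan
            premature = first < 0.1
        else:
            licks = np.zeros(0)
            outcome = "miss" if kind == "stimulus" else "correct_rejection"
            reward, premature = np.nan, False
        rows["kind"].append(kind); rows["onset"].append(onset)
        rows["licks"].append(licks); rows["outcome"].append(outcome)
        rows["premature"].append(premature); rows["light"].append(light)
        rows["reward"].append(reward)
    return TrialTable(
        np.arange(n), np.array(rows["kind"], object), np.array(rows["onset"]),
        rows["licks"], np.array(rows["outcome"], object),
        np.array(rows["premature"]), np.array(rows["light"]),
        np.array(rows["reward"]))


def _simulate_neutral_session(scenario: CohortScenario, rng) -> TrialTable:
    """Stimulus schedule as in the detection task; the lick process is
    a session-long Poisson train statistically independent of the
    stimulus times."""
    n = scenario.trials_per_session
    onsets = np.cumsum(rng.uniform(6.0, 12.0, size=n))
    duration = onsets[-1] + 6.0
    n_licks = rng.poisson(scenario.neutral_lick_hz * duration)
    lick_abs = np.sort(rng.uniform(0.0, duration, size=n_licks))
    kinds = np.where(rng.random(n) >= scenario.catch_prob, "stimulus", "catch")
    licks, outcomes, premature = [], [], []
    for i in range(n):
        rel = lick_abs[(lick_abs >= onsets[i] - 4.0)
                       & (lick_abs < onsets[i] + 2.0)] - onsets[i]
        licks.append(rel)
        outcomes.append("unclassified")
        premature.append(False)
    t = TrialTable(np.arange(n), kinds.astype(object), onsets, licks,
                   np.array(outcomes, object), np.array(premature),
                   np.zeros(n, bool), np.full(n, np.nan))
    return classify_trials(t)


def simulate_behavior(scenario: CohortScenario):
    """Generate all behavioral sessions of a cohort.

    Returns a list of ``(SessionMeta, TrialTable)``.  For the standard
    paradigms there is one session per mouse per day; for manipulation
    scenarios there is one session per (mouse, target area) for the
    manipulated condition, plus Ringer controls for muscimol.
    """
    scenario.validate()
    sessions = []
    if scenario.opto_hit_effect:
        for m in range(scenario.n_mice):
            for ai, area in enumerate(scenario.areas):
                if area not in scenario.opto_hit_effect:
                    continue
                rng = _rng(scenario, "behavior", m, ai)
                t = _simulate_detection_session(
                    scenario, rng,
                    hit_mult_light=scenario.opto_hit_effect[area],
                    fa_mult_light=scenario.opto_fa_effect.get(area, 1.0),
                    day=scenario.n_days, with_light=True)
                meta = SessionMeta(f"mouse{m:02d}", scenario.n_days,
                                   "detection", "opto", area)
                sessions.append((meta, t))
        return sessions
    if scenario.muscimol_hit_effect:
        areas = [a for a in scenario.areas if a in scenario.muscimol_hit_effect]
        for ai, area in enumerate(areas):
            for m in range(scenario.n_mice):
                rng = _rng(scenario, "behavior", m, ai)
                t = _simulate_detection_session(
                    scenario, rng, hit_mult_all=scenario.muscimol_hit_effect[area],
                    day=scenario.n_days)
                meta = SessionMeta(f"mouse{ai}{m:02d}", scenario.n_days,
                                   "detection", "muscimol", area)
                sessions.append((meta, t))
        # pooled Ringer control group, injections spread across areas
        for m in range(scenario.n_mice):
            rng = _rng(scenario, "behavior", m, 900)
            t = _simulate_detection_session(scenario, rng, day=scenario.n_days)
            meta = SessionMeta(f"ctrl{m:02d}", scenario.n_days,
                               "detection", "ringer", areas[m % len(areas)])
            sessions.append((meta, t))
        return sessions

    for m in range(scenario.n_mice):
        for day in range(1, scenario.n_days + 1):
            rng = _rng(scenario, "behavior", m, day)
            if scenario.paradigm == "neutral_exposure":
                t = _simulate_neutral_session(scenario, rng)
            else:
                t = _simulate_detection_session(scenario, rng, day=day)
            meta = SessionMeta(f"mouse{m:02d}", day, scenario.paradigm, "none")
            sessions.append((meta, t))
    return sessions


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _solve_tau_rise(peak_offset_ms: float, tau_decay_ms: float) -> float:
    """Rise constant of a difference of exponentials with the requested
    time-to-peak; time-to-peak is increasing in tau_rise on (0, tau_d)."""
    def t_peak(tr):
        return tr * tau_decay_ms / (tau_decay_ms - tr) * np.log(tau_decay_ms / tr)
    return brentq(lambda tr: t_peak(tr) - peak_offset_ms,
                  1e-4, tau_decay_ms - 1e-4)


def evoked_kernel(kernel: SEPKernel, fs_hz: float,
                  duration_s: float = 0.4) -> np.ndarray:
    """Sampled evoked kernel with unit peak magnitude, signed by
    polarity; sample 0 is the stimulus onset."""
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz * 1e3  # ms
    lat, td = kernel.latency_ms, kernel.tau_decay_ms
    tr = _solve_tau_rise(kernel.peak_ms - lat, td)
    s = t - lat
    y = np.where(s >= 0, np.exp(-np.maximum(s, 0) / td)
                 - np.exp(-np.maximum(s, 0) / tr), 0.0)
    y /= np.abs(y).max()
    return kernel.polarity * y


#: Amplitude (µV) of the injected 1 ms stimulus artifact.
ARTIFACT_UV = 4000.0


def simulate_lfp(trials: TrialTable, scenario: CohortScenario,
                 day_dprime: float,
                 rng: np.random.Generator | None = None,
                 areas: list | None = None) -> ContinuousRecording:
    """Continuous multi-area LFP for one session.

    Each stimulus trial adds the area kernel scaled to
    ``base + gain * day_dprime`` µV (clipped at 0), further scaled by
    ``1 + hit_gain`` on hit trials and by a per-session lognormal gain
    (day-to-day response variability); in the neutral-exposure paradigm
    both the d' coupling and the hit gain are forced to zero.  Noise is
    additive AR(1) Gaussian; a 1 ms artifact impulse is injected at
    every stimulus onset to exercise artifact removal.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    fs = scenario.fs_hz
    areas = list(scenario.areas if areas is None else areas)
    duration = float(trials.onset_s[-1]) + 3.0 if len(trials) else 3.0
    n_samp = int(round(duration * fs))
    ar = scenario.noise.ar1
    innov_sd = scenario.noise.std_uv * np.sqrt(1.0 - ar ** 2)
    neutral = scenario.paradigm == "neutral_exposure"

    stim = (trials.kind == "stimulus") & (trials.outcome != "aborted")
    stim_idx = np.flatnonzero(stim)
    onset_samples = np.round(trials.onset_s * fs).astype(int)
    session_gain = (float(rng.lognormal(0.0, scenario.noise.session_gain_sd))
                    if scenario.noise.session_gain_sd > 0 else 1.0)

    samples = np.empty((len(areas), n_samp), dtype=np.float32)
    from scipy.signal import lfilter
    for ci, area in enumerate(areas):
        white = rng.standard_normal(n_samp, dtype=np.float32) * np.float32(innov_sd)
        trace = lfilter(np.array([1.0], np.float32),
                        np.array([1.0, -ar], np.float32), white)
        kern = evoked_kernel(scenario.kernel[area], fs)
        coup = scenario.coupling[area]
        gain = 0.0 if neutral else coup.dprime_gain_uv
        hit_gain = 0.0 if neutral else coup.hit_gain
        for ti in stim_idx:
            amp = session_gain * max(0.0, coup.base_uv + gain * day_dprime)
            if trials.outcome[ti] == "hit":
                amp *= 1.0 + hit_gain
            s0 = onset_samples[ti]
            seg = min(len(kern), n_samp - s0)
            if seg > 0:
                trace[s0:s0 + seg] += amp * kern[:seg]
        # 1 ms stimulus artifact impulse at onset
        n_art = max(1, int(round(0.001 * fs)))
        for ti in stim_idx:
            s0 = onset_samples[ti]
            trace[s0:min(s0 + n_art, n_samp)] += ARTIFACT_UV
        samples[ci] = trace
    return ContinuousRecording(samples=samples, fs_hz=fs,
                               channel_area={ci: a for ci, a in enumerate(areas)},
                               t0_s=0.0)


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def simulate_spikes(trials: TrialTable, scenario: CohortScenario,
                    rng: np.random.Generator | None = None):
    """Inhomogeneous-Poisson units with post-onset rate modulation.

    Unit classes (positive / negative / unmodulated) are assigned in
    the exact programmed proportions.  On stimulus trials, positive
    units increase and negative units decrease their rate in the 1 s
    post-onset window, with a deeper modulation on hit than miss
    trials.  Trough-to-peak durations are drawn from an RSU/FSU
    mixture.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    sp = scenario.spikes
    n_units = sp.n_units
    n_pos = int(round(sp.frac_positive * n_units))
    n_neg = int(round(sp.frac_negative * n_units))
    klasses = np.array(["positive"] * n_pos + ["negative"] * n_neg
                       + ["none"] * (n_units - n_pos - n_neg), dtype=object)
    rng.shuffle(klasses)

    duration = float(trials.onset_s[-1]) + 3.0 if len(trials) else 3.0
    stim = (trials.kind == "stimulus") & (trials.outcome != "aborted")
    stim_onsets = trials.onset_s[stim]
    stim_is_hit = trials.outcome[stim] == "hit"

    units = []
    for u in range(n_units):
        base = sp.baseline_hz
        spikes = np.sort(rng.uniform(0.0, duration, rng.poisson(base * duration)))
        klass = klasses[u]
        if klass != "none":
            sign = 1.0 if klass == "positive" else -1.0
            for onset, is_hit in zip(stim_onsets, stim_is_hit):
                depth = sp.modulation_depth * (1.0 if is_hit
                                               else sp.miss_depth_fraction)
                target = max(0.0, base * (1.0 + sign * depth))
                in_win = (spikes >= onset) & (spikes < onset + 1.0)
                if sign > 0:
                    extra = rng.uniform(onset, onset + 1.0,
                                        rng.poisson(target - base))
                    spikes = np.concatenate([spikes, extra])
                else:
                    keep_p = target / base if base > 0 else 0.0
                    drop = in_win & (rng.random(len(spikes)) >= keep_p)
                    spikes = spikes[~drop]
            spikes = np.sort(spikes)
        is_fsu = rng.random() < sp.fsu_fraction
        mean_dur = sp.fsu_duration_ms if is_fsu else sp.rsu_duration_ms
        dur = max(0.05, rng.normal(mean_dur, sp.duration_sd_ms))
        wf_fs = 30000.0
        wt = np.arange(int(wf_fs * 0.003)) / wf_fs * 1e3  # ms
        wf = -np.exp(-((wt - 0.4) / 0.1) ** 2) + 0.5 * np.exp(
            -((wt - 0.4 - dur) / (0.3 * dur + 0.05)) ** 2)
        units.append(UnitData(
            unit_id=f"u{u:03d}", spike_times_s=spikes, waveform=wf,
            waveform_fs_hz=wf_fs, trough_to_peak_ms=dur, area="mPFC"))
    return units


# ---------------------------------------------------------------------------
# Cohort writer
# ---------------------------------------------------------------------------

def make_cohort(scenario: CohortScenario, out_dir,
                include_spikes: bool = True):
    """Write all sessions of a cohort to ``out_dir`` via the HDF5
    container, plus a manifest CSV (mouse, day, paradigm, seed, path)."""
    scenario.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, paths = [], []
    for m_i, (meta, trials) in enumerate(simulate_behavior(scenario)):
        perf = session_performance(trials, day_index=meta.day_index)
        mouse_num = int("".join(c for c in meta.mouse_id if c.isdigit()) or 0)
        lfp = simulate_lfp(trials, scenario, perf.dprime,
                           _rng(scenario, "lfp", mouse_num, meta.day_index, m_i))
        units = (simulate_spikes(trials, scenario,
                                 _rng(scenario, "spikes", mouse_num,
                                      meta.day_index, m_i))
                 if include_spikes else [])
        name = f"{meta.mouse_id}_day{meta.day_index:02d}"
        if meta.manipulation != "none":
            name += f"_{meta.manipulation}_{meta.target_area}"
        path = out_dir / f"{name}.h5"
        write_session(meta, trials, lfp, units, path)
        paths.append(path)
        rows.append({"mouse": meta.mouse_id, "day": meta.day_index,
                     "paradigm": meta.paradigm,
                     "manipulation": meta.manipulation,
                     "target_area": meta.target_area or "",
                     "seed": scenario.seed, "path": path.name})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return paths
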