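"""Sensory-evoked potential (SEP) extraction, averaging and comparison.

The continuous LFP is cleaned (stimulus-artifact blanking, zero-phase
0.1–100 Hz band-pass), epoched around trial onsets (catch trials on
their scheduled virtual onsets), baseline-corrected over the 50 ms
before onset, and averaged into per-condition SEPs.  Per-session first
peaks are detected as the earliest supra-noise local extremum of the
area's polarity; condition contrasts (first day vs trained, hit vs
miss) are then measured at that fixed peak time.  Statistical
comparisons use the Wilcoxon signed-rank test in sliding 5 ms windows,
Pearson correlation (with t statistic) of peak amplitude against d',
and the joint-rank pairwise procedure for across-area latency/peak
orderings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import stats
from .data_model import ContinuousRecording, TrialTable

__all__ = [
    "EpochArray", "SEPResult",
    "preprocess_lfp", "extract_epochs", "average_sep",
    "find_first_peak", "measure_at", "onset_latency",
    "windowed_paired_test", "peak_vs_dprime_correlation",
    "latency_ordering_test", "AREA_POLARITY",
]

#: First-peak polarity searched per area: the early evoked deflection
#: is negative (depolarizing-compatible) everywhere except mPFC.
AREA_POLARITY = {"wS1": -1, "wS2": -1, "wM1": -1,
                 "PtA": -1, "dCA1": -1, "mPFC": +1}

BAND_HZ = (0.1, 100.0)
ARTIFACT_BLANK_S = (0.0, 0.002)
BASELINE_S = (-0.05, 0.0)
EPOCH_S = (-0.05, 0.3)


@dataclass
class EpochArray:
    """Baseline-corrected single-trial LFP epochs for one area.

    ``data`` is (n_trials, n_time) in µV; ``time_s`` is relative to
    the trial onset; ``trial_ids`` aligns rows to the trial table.
    """

    data: np.ndarray
    time_s: np.ndarray
    area: str
    trial_ids: np.ndarray

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time_s)))


@dataclass
class SEPResult:
    """Trial-averaged evoked waveform with per-sample SEM."""

    waveform: np.ndarray
    sem: np.ndarray
    time_s: np.ndarray
    n_trials: int
    area: str = ""
    peak_time_s: float | None = None
    peak_amp_uv: float | None = None
    onset_latency_s: float | None = None


# ---------------------------------------------------------------------------
# Preprocessing and epoching
# ---------------------------------------------------------------------------

def preprocess_lfp(rec: ContinuousRecording, stim_times_s) -> ContinuousRecording:
    """Blank the stimulus artifact, then zero-phase band-pass filter.

    The artifact window [0, 2] ms after each stimulus time is replaced
    by linear interpolation between the bracketing samples; all
    channels are then filtered 0.1–100 Hz with a 4th-order Butterworth
    applied forward-backward.
    """
    if rec.fs_hz < 500:
        raise ValueError("sampling rate must be >= 500 Hz")
    stim_times_s = np.asarray(stim_times_s, dtype=float)
    # Keep the simulator's compact dtype: filtering in float32 is ~6x
    # faster and its error (~µV) is negligible against the signals.
    work_dtype = (np.float32 if rec.samples.dtype == np.float32
                  else np.float64)
    data = rec.samples.astype(work_dtype).copy()
    n = data.shape[1]
    for t in stim_times_s:
        s = t - rec.t0_s
        if not 0.0 <= s < rec.duration_s:
            raise ValueError(f"stimulus time {t} s outside the recording")
        i0 = int(np.floor(s * rec.fs_hz)) - 1
        i1 = int(np.ceil((s + ARTIFACT_BLANK_S[1]) * rec.fs_hz)) + 1
        i0 = max(i0, 0)
        i1 = min(i1, n - 1)
        span = i1 - i0
        if span > 1:
            w = np.arange(1, span) / span
            data[:, i0 + 1:i1] = (data[:, [i0]] * (1 - w)
                                  + data[:, [i1]] * w)
    nyq = rec.fs_hz / 2.0
    sos = butter(4, [BAND_HZ[0] / nyq, BAND_HZ[1] / nyq], btype="band",
                 output="sos").astype(work_dtype)
    data = sosfiltfilt(sos, data, axis=1)
    return ContinuousRecording(samples=data, fs_hz=rec.fs_hz,
                               channel_area=dict(rec.channel_area),
                               t0_s=rec.t0_s)


def extract_epochs(rec: ContinuousRecording, trials: TrialTable, area: str,
                   window: tuple = EPOCH_S,
                   baseline: tuple = BASELINE_S) -> EpochArray:
    """Per-trial epochs for one area, each minus its own baseline mean.

    Catch trials are epoched on their scheduled virtual onsets.  Trials
    whose window exceeds the recording bounds are dropped with a
    warning.
    """
    ch = rec.channel_of(area)
    fs = rec.fs_hz
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    time_s = np.arange(i_lo, i_hi) / fs
    b_lo = int(round(baseline[0] * fs)) - i_lo
    b_hi = int(round(baseline[1] * fs)) - i_lo

    rows, kept = [], []
    n = rec.n_samples
    dropped = 0
    for i in range(len(trials)):
        s0 = int(round((trials.onset_s[i] - rec.t0_s) * fs))
        if s0 + i_lo < 0 or s0 + i_hi > n:
            dropped += 1
            continue
        ep = rec.samples[ch, s0 + i_lo:s0 + i_hi].astype(float)
        ep = ep - ep[b_lo:b_hi].mean()
        rows.append(ep)
        kept.append(trials.trial_id[i])
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) with epochs outside the "
                      "recording", stacklevel=2)
    data = np.array(rows) if rows else np.zeros((0, i_hi - i_lo))
    return EpochArray(data=data, time_s=time_s, area=area,
                      trial_ids=np.asarray(kept, dtype=np.int64))


# ---------------------------------------------------------------------------
# Averaging and measurement
# ---------------------------------------------------------------------------

def average_sep(epochs: EpochArray, mask=None) -> SEPResult:
    """Pointwise mean and SEM over the selected trials.

    Hit-trial masks must be built excluding premature trials; this
    function averages whatever mask it is given.
    """
    if mask is None:
        mask = np.ones(len(epochs.data), dtype=bool)
    mask = np.asarray(mask)
    sel = epochs.data[mask]
    if len(sel) == 0:
        raise ValueError("empty trial selection")
    wave = sel.mean(axis=0)
    sem = (sel.std(axis=0, ddof=1) / np.sqrt(len(sel))
           if len(sel) > 1 else np.zeros_like(wave))
    return SEPResult(waveform=wave, sem=sem, time_s=epochs.time_s,
                     n_trials=len(sel), area=epochs.area)


def hit_mask(trials: TrialTable, trial_ids) -> np.ndarray:
    """Mask of non-premature hit trials aligned to epoch rows."""
    by_id = {tid: i for i, tid in enumerate(trials.trial_id)}
    out = np.zeros(len(trial_ids), dtype=bool)
    for r, tid in enumerate(trial_ids):
        i = by_id[tid]
        out[r] = trials.outcome[i] == "hit" and not trials.premature[i]
    return out


def _noise_scale(sep: SEPResult) -> float:
    """Noise level of the averaged waveform.

    The per-epoch baseline correction whitens the baseline segment of
    the average, so its SD alone underestimates the ripple left in the
    rest of the waveform; the per-sample SEM is the direct estimate of
    that ripple.  The scale used is the larger of the two (SEM is zero
    when unavailable, degrading gracefully to the baseline SD).
    """
    base = sep.waveform[(sep.time_s >= BASELINE_S[0]) & (sep.time_s < BASELINE_S[1])]
    base_sd = float(base.std(ddof=1)) if len(base) > 1 else 0.0
    sem = float(np.median(sep.sem)) if sep.sem is not None and len(sep.sem) else 0.0
    return max(base_sd, sem)


def find_first_peak(sep: SEPResult, polarity: int,
                    search: tuple = (0.003, 0.1), k_sd: float = 2.0):
    """Earliest local extremum of the given polarity in the search
    window whose magnitude exceeds ``k_sd`` × the baseline SD of the
    averaged waveform.

    The search is anchored at the response onset (the first sustained
    supra-threshold crossing, as in :func:`onset_latency`) when one
    exists, which keeps isolated pre-response noise ripples — which can
    exceed the threshold when heavy averaging makes the baseline SD
    tiny — from being mistaken for the first peak.  Returns
    ``(peak_time_s, peak_amp_uv)`` or ``(None, None)`` when no sample
    qualifies.
    """
    y = polarity * sep.waveform
    t = sep.time_s
    thresh = k_sd * _noise_scale(sep)
    start = search[0]
    onset = onset_latency(sep, k_sd=k_sd)
    if onset is not None:
        start = max(start, onset)
    in_win = (t >= start) & (t < search[1])
    idx = np.flatnonzero(in_win)
    for i in idx:
        if i == 0 or i == len(y) - 1:
            continue
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > thresh:
            return float(t[i]), float(sep.waveform[i])
    return None, None


def measure_at(sep: SEPResult, t_ref_s: float) -> float:
    """Waveform amplitude (µV) at the sample nearest ``t_ref_s``.

    Used to compare conditions (hit vs miss, first day vs trained) at
    the peak time fixed from the reference condition.
    """
    if not sep.time_s[0] <= t_ref_s <= sep.time_s[-1]:
        raise ValueError(f"t_ref {t_ref_s} s outside waveform support")
    i = int(np.argmin(np.abs(sep.time_s - t_ref_s)))
    return float(sep.waveform[i])


def onset_latency(sep: SEPResult, k_sd: float = 2.0,
                  min_run_ms: float = 5.0):
    """First time after onset where |waveform| stays above
    ``k_sd`` × baseline SD for at least ``min_run_ms``; ``None`` when
    the threshold is never held that long."""
    sd = _noise_scale(sep)
    if sd == 0:
        return None
    fs = 1.0 / float(np.mean(np.diff(sep.time_s)))
    run = max(1, int(round(min_run_ms * 1e-3 * fs)))
    above = (np.abs(sep.waveform) > k_sd * sd) & (sep.time_s >= 0)
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= run:
            return float(sep.time_s[i - run + 1])
    return None


# ---------------------------------------------------------------------------
# Statistics across mice
# ---------------------------------------------------------------------------

def windowed_paired_test(per_mouse_pairs: list, time_s: np.ndarray,
                         win_ms: float = 5.0):
    """Per-window paired Wilcoxon test between two conditions.

    ``per_mouse_pairs`` is a list of (waveform_A, waveform_B) per
    mouse, on the common ``time_s`` grid.  Each 5 ms window yields a
    per-mouse mean amplitude for A and B and a paired signed-rank
    p-value across mice; p-values are reported per window without
    correction (mirroring a color-coded significance display).
    Returns ``(window_centers_s, pvals)``.
    """
    n_mice = len(per_mouse_pairs)
    if n_mice < 2:
        raise ValueError("need at least 2 mice for a paired test")
    if n_mice < 5:
        warnings.warn("fewer than 5 mice: the signed-rank test cannot reach "
                      "p < 0.05 two-sided", stacklevel=2)
    win_s = win_ms * 1e-3
    t0 = time_s[0]
    n_win = int(np.floor((time_s[-1] - t0) / win_s))
    centers, pvals = [], []
    for w in range(n_win):
        lo, hi = t0 + w * win_s, t0 + (w + 1) * win_s
        sel = (time_s >= lo) & (time_s < hi)
        a = np.array([p[0][sel].mean() for p in per_mouse_pairs])
        b = np.array([p[1][sel].mean() for p in per_mouse_pairs])
        centers.append((lo + hi) / 2.0)
        pvals.append(stats.wilcoxon_signed_rank(a, b))
    return np.asarray(centers), np.asarray(pvals)


def peak_vs_dprime_correlation(peak_amp, dprime):
    """Pearson correlation of peak amplitude against d' with the
    two-sided p-value from t = r sqrt(n-2)/sqrt(1-r²) on n-2 df.

    Points are pooled over (mouse, day).  Returns ``(r, p, n)``.
    """
    from scipy.stats import t as t_dist
    x = np.asarray(dprime, dtype=float)
    y = np.asarray(peak_amp, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in correlation input")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t_stat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return r, p, n


def latency_ordering_test(latencies_by_area: dict, alpha: float = 0.05):
    """Pairwise across-area comparison of per-mouse latencies (or peak
    times) via the joint-ranking multiple-comparison procedure."""
    labels = list(latencies_by_area)
    groups = [np.asarray(latencies_by_area[a], dtype=float) for a in labels]
    return stats.dunn_holland_wolfe(groups, labels=labels, alpha=alpha)
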