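"""PSTHs, unit classification, and resampling tests of rate modulation.

Units are classified as regular-spiking (RSU, putative excitatory) or
fast-spiking (FSU, putative inhibitory) by the trough-to-peak duration
of their mean waveform.  Stimulus modulation is assessed per unit by
comparing the mean firing rate across hit trials in the 1 s window
after trial onset with the 1 s window before onset: trials are
bootstrapped 1000 times and the distribution of post−pre rate
differences is compared to zero, splitting the two-sided level between
the positive and negative directions.  Hit-vs-miss differences in the
post-onset rate are tested by permutation of trial labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import UnitData

__all__ = [
    "ModulationResult", "classify_unit", "psth", "zscore_psth",
    "modulation_test", "hit_miss_unit_test", "population_summary",
    "trial_window_counts",
]

#: RSU/FSU split on waveform trough-to-peak duration (ms); at or above
#: the threshold is RSU.
RSU_THRESHOLD_MS = 0.35

PRE_WINDOW_S = (-1.0, 0.0)
POST_WINDOW_S = (0.0, 1.0)


@dataclass
class ModulationResult:
    unit_id: str
    mean_pre_hz: float
    mean_post_hz: float
    delta_hz: float
    p_boot: float
    klass: str  # positive / negative / none


def classify_unit(trough_to_peak_ms: float,
                  threshold_ms: float = RSU_THRESHOLD_MS) -> str:
    """RSU if the waveform duration is at or above threshold, else FSU."""
    if not trough_to_peak_ms > 0:
        raise ValueError("waveform duration must be positive")
    return "RSU" if trough_to_peak_ms >= threshold_ms else "FSU"


def trial_window_counts(unit: UnitData, onsets_s, window) -> np.ndarray:
    """Spike counts per trial in ``[onset + window[0], onset + window[1])``."""
    onsets = np.asarray(onsets_s, dtype=float)
    t = unit.spike_times_s
    lo = np.searchsorted(t, onsets + window[0], side="left")
    hi = np.searchsorted(t, onsets + window[1], side="left")
    return (hi - lo).astype(float)


def psth(unit: UnitData, onsets_s, window=(-1.0, 2.0),
         bin_ms: float = 10.0):
    """Trial-averaged firing rate: counts per bin across trials divided
    by (n_trials × bin width).  Returns ``(bin_centers_s, rate_hz)``;
    an empty spike train yields an all-zero curve.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if len(onsets) == 0:
        raise ValueError("need at least one trial onset")
    bw = bin_ms * 1e-3
    edges = np.arange(window[0], window[1] + bw / 2, bw)
    counts = np.zeros(len(edges) - 1)
    for o in onsets:
        rel = unit.spike_times_s[(unit.spike_times_s >= o + window[0])
                                 & (unit.spike_times_s < o + window[1])] - o
        counts += np.histogram(rel, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / (len(onsets) * bw)


def zscore_psth(centers_s, rate_hz, baseline=(-1.0, 0.0)):
    """(rate − baseline mean) / baseline SD per bin."""
    centers_s = np.asarray(centers_s)
    rate_hz = np.asarray(rate_hz, dtype=float)
    base = rate_hz[(centers_s >= baseline[0]) & (centers_s < baseline[1])]
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline SD; widen the baseline window or "
                         "exclude the unit")
    return (rate_hz - base.mean()) / sd


def modulation_test(unit: UnitData, hit_onsets_s, n_boot: int = 1000,
                    seed: int = 0, alpha: float = 0.05) -> ModulationResult:
    """Bootstrap test of post-vs-pre rate modulation across hit trials.

    Per-trial differences of the 1 s post- and pre-onset rates are
    resampled (trials with replacement, ``n_boot`` times); the unit is
    positively modulated when the fraction of bootstrap mean
    differences ≤ 0 falls below alpha/2, negatively when the fraction
    ≥ 0 does.  Deterministic given ``seed``.
    """
    onsets = np.asarray(hit_onsets_s, dtype=float)
    if len(onsets) < 10:
        raise ValueError("need at least 10 trials for the bootstrap test")
    pre = trial_window_counts(unit, onsets, PRE_WINDOW_S)
    post = trial_window_counts(unit, onsets, POST_WINDOW_S)
    diffs = post - pre  # Hz, since both windows last 1 s
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
    boot_means = diffs[idx].mean(axis=1)
    p_pos = float(np.mean(boot_means <= 0.0))
    p_neg = float(np.mean(boot_means >= 0.0))
    if p_pos < alpha / 2:
        klass = "positive"
    elif p_neg < alpha / 2:
        klass = "negative"
    else:
        klass = "none"
    return ModulationResult(
        unit_id=unit.unit_id, mean_pre_hz=float(pre.mean()),
        mean_post_hz=float(post.mean()), delta_hz=float(diffs.mean()),
        p_boot=min(p_pos, p_neg), klass=klass)


def hit_miss_unit_test(unit: UnitData, hit_onsets_s, miss_onsets_s,
                       n_perm: int = 1000, seed: int = 0,
                       alpha: float = 0.05):
    """Hit−miss difference of the post-onset (0–1 s) rate, tested by
    two-sided permutation of trial labels.  Returns
    ``(delta_hz, significant)``."""
    hits = np.asarray(hit_onsets_s, dtype=float)
    misses = np.asarray(miss_onsets_s, dtype=float)
    if len(hits) == 0 or len(misses) == 0:
        raise ValueError("both hit and miss trials are required")
    if min(len(hits), len(misses)) < 5:
        raise ValueError("need at least 5 trials per class")
    h = trial_window_counts(unit, hits, POST_WINDOW_S)
    m = trial_window_counts(unit, misses, POST_WINDOW_S)
    delta = float(h.mean() - m.mean())
    pooled = np.concatenate([h, m])
    n_h = len(h)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        d = pooled[perm[:n_h]].mean() - pooled[perm[n_h:]].mean()
        if abs(d) >= abs(delta) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return delta, p < alpha


def population_summary(results: list):
    """Fractions (positive, negative, none) over units, with counts.

    Returns a dict with ``frac_*`` and ``n_*`` entries.
    """
    if not results:
        raise ValueError("no modulation results")
    n = len(results)
    n_pos = sum(r.klass == "positive" for r in results)
    n_neg = sum(r.klass == "negative" for r in results)
    n_none = n - n_pos - n_neg
    return {"n_units": n, "n_positive": n_pos, "n_negative": n_neg,
            "n_none": n_none, "frac_positive": n_pos / n,
            "frac_negative": n_neg / n, "frac_none": n_none / n}
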