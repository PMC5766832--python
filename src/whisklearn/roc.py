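"""Time-resolved ROC "Stimulus Probability" decoding from single-trial LFP.

For each 10 ms window (slid in 2.5 ms steps) the distribution of
single-trial mean LFP amplitudes on stimulus trials is compared with
the catch-trial distribution; the area under the ROC curve is the
Stimulus Probability (SP) for that window.  Chance bands come from
recomputing the curve under 100 random permutations of the trial
labels.  SP equals the Mann-Whitney U statistic normalized by the
number of trial pairs, with ties counted as 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sep import EpochArray

__all__ = ["SPCurve", "window_features", "auc", "sp_curve",
           "grand_average_sp"]

WIN_MS = 10.0
STEP_MS = 2.5
N_SHUFFLE = 100


@dataclass
class SPCurve:
    """Stimulus Probability vs time with its shuffle baseline."""

    time_s: np.ndarray
    sp: np.ndarray
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    n_stim: int
    n_catch: int
    area: str = ""


def window_features(epochs: EpochArray, win_ms: float = WIN_MS,
                    step_ms: float = STEP_MS):
    """Sliding-window mean amplitudes.

    Each feature is the mean LFP over ``[t, t + win)`` ms; the window
    is labeled by its center.  Returns ``(features, centers_s)`` with
    ``features`` of shape (n_trials, n_windows).  The first window
    begins at the epoch start; the step must be a whole number of
    sample periods.
    """
    fs = epochs.fs_hz
    step = step_ms * 1e-3 * fs
    win = win_ms * 1e-3 * fs
    if abs(step - round(step)) > 1e-6:
        raise ValueError(
            f"step of {step_ms} ms is not a whole number of samples at "
            f"fs = {fs:.0f} Hz; choose a step that is a multiple of "
            f"{1e3 / fs:.3f} ms")
    step = int(round(step))
    win = int(round(win))
    n_time = epochs.data.shape[1]
    if win > n_time:
        raise ValueError("epoch shorter than one window")
    n_win = (n_time - win) // step + 1
    # cumulative sums give every window mean in O(1)
    cs = np.cumsum(epochs.data, axis=1)
    cs = np.concatenate([np.zeros((len(epochs.data), 1)), cs], axis=1)
    starts = np.arange(n_win) * step
    feats = (cs[:, starts + win] - cs[:, starts]) / win
    centers = epochs.time_s[0] + (starts + win / 2.0) / fs
    return feats, centers


def auc(stim_values, catch_values) -> float:
    """Area under the ROC of stimulus vs catch value distributions.

    Equals (#pairs with stim > catch + half the ties) / (n_s · n_c),
    i.e. the Mann-Whitney U statistic divided by the pair count.
    """
    s = np.asarray(stim_values, dtype=float)
    c = np.asarray(catch_values, dtype=float)
    if len(s) == 0 or len(c) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = _midranks_columns(np.concatenate([s, c])[:, None])
    return float(_auc_from_ranks(ranks, np.arange(len(s)))[0])


def _midranks_columns(pooled: np.ndarray) -> np.ndarray:
    """Column-wise midranks (1..n, ties averaged) of a
    (n_trials, n_windows) feature matrix."""
    from scipy.stats import rankdata
    return rankdata(pooled, axis=0, method="average")


def _auc_from_ranks(ranks: np.ndarray, stim_rows: np.ndarray) -> np.ndarray:
    """Column-wise AUC from precomputed joint midranks:
    AUC = (R_stim - n_s(n_s+1)/2) / (n_s n_c)."""
    n = ranks.shape[0]
    n_s = len(stim_rows)
    n_c = n - n_s
    r_stim = ranks[stim_rows].sum(axis=0)
    return (r_stim - n_s * (n_s + 1) / 2.0) / (n_s * n_c)


def sp_curve(epochs: EpochArray, stim_labels, n_shuffle: int = N_SHUFFLE,
             seed: int = 0, win_ms: float = WIN_MS,
             step_ms: float = STEP_MS, polarity: int = 1) -> SPCurve:
    """Stimulus Probability curve with a label-shuffle chance band.

    ``stim_labels`` is a boolean array (True = stimulus trial) aligned
    to the epoch rows.  ``polarity`` aligns the features with the
    area's evoked-response direction (−1 for areas whose evoked
    deflection is negative) so that a detectable response always drives
    SP above 0.5; the sign flip leaves the shuffle null unchanged.  The
    shuffle baseline is the per-window mean and SD of the AUC over
    ``n_shuffle`` random label permutations within the session;
    deterministic given ``seed``.
    """
    labels = np.asarray(stim_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both stimulus and catch trials are required")
    feats, centers = window_features(epochs, win_ms, step_ms)
    feats = polarity * feats
    stim_rows = np.flatnonzero(labels)
    ranks = _midranks_columns(feats)
    sp = _auc_from_ranks(ranks, stim_rows)

    rng = np.random.default_rng(seed)
    n = len(labels)
    shuffled = np.empty((n_shuffle, feats.shape[1]))
    for k in range(n_shuffle):
        perm = rng.permutation(n)
        shuffled[k] = _auc_from_ranks(ranks, perm[:len(stim_rows)])
    return SPCurve(time_s=centers, sp=sp,
                   shuffle_mean=shuffled.mean(axis=0),
                   shuffle_sd=shuffled.std(axis=0, ddof=1),
                   n_stim=int(labels.sum()), n_catch=int(n - labels.sum()),
                   area=epochs.area)


def grand_average_sp(curves: list):
    """Pointwise mean ± SEM of SP curves across mice.

    All curves must share one time grid.  Returns
    ``(time_s, mean, sem)``; SEM is zero for a single curve.
    """
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].time_s
    for c in curves[1:]:
        if len(c.time_s) != len(t0) or np.max(np.abs(c.time_s - t0)) > 1e-9:
            raise ValueError("SP curves are on different time grids")
    sp = np.array([c.sp for c in curves])
    mean = sp.mean(axis=0)
    sem = (sp.std(axis=0, ddof=1) / np.sqrt(len(curves))
           if len(curves) > 1 else np.zeros_like(mean))
    return t0, mean, sem
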