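"""Trial classification, signal-detection performance, session selection.

Performance on the go/no-go detection task is summarized per session by
the hit rate (licks within the 1 s response window on stimulus trials),
the false-alarm rate (same window on catch trials), and the sensitivity

    d' = Z(hit rate) - Z(false-alarm rate),

with Z the inverse standard-normal CDF.  The loglinear correction
(add 0.5 to the hit and false-alarm counts and 1 to the trial counts)
is applied systematically so d' stays finite at extreme rates.

Analysis sessions for trained animals are the first three training days
with day index > 4 and d' > 1; for the neutral-exposure paradigm the
last three exposure days are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .data_model import TrialTable, ValidationError

__all__ = [
    "RESPONSE_WINDOW_S",
    "PREMATURE_S",
    "SessionPerformance",
    "classify_trials",
    "dprime",
    "session_performance",
    "select_trained_sessions",
    "select_exposed_sessions",
    "performance_table",
]

#: Response window after stimulus (or virtual catch) onset, seconds.
RESPONSE_WINDOW_S = 1.0
#: Licks earlier than this after onset are flagged premature.
PREMATURE_S = 0.1


@dataclass
class SessionPerformance:
    """Counts, rates and loglinear d' for one session."""

    n_stim: int
    n_catch: int
    n_hit: int
    n_fa: int
    hit_rate: float
    fa_rate: float
    dprime: float
    day_index: int = 0


def classify_trials(trials: TrialTable) -> TrialTable:
    """Fill trial outcomes from lick times.

    A stimulus trial with at least one lick in ``[0, 1)`` s is a hit
    (premature if the first in-window lick falls before 100 ms),
    otherwise a miss; a catch trial with an in-window lick is a false
    alarm, otherwise a correct rejection.  Trials already marked
    aborted are left untouched and excluded from rate denominators
    downstream.
    """
    if np.any(~np.isfinite(trials.onset_s)):
        raise ValidationError("onset_s: missing or non-finite onset")
    outcome = trials.outcome.copy()
    premature = trials.premature.copy()
    for i in range(len(trials)):
        if outcome[i] == "aborted":
            continue
        licks = trials.lick_times_s[i]
        in_win = licks[(licks >= 0.0) & (licks < RESPONSE_WINDOW_S)]
        licked = len(in_win) > 0
        if trials.kind[i] == "stimulus":
            outcome[i] = "hit" if licked else "miss"
        else:
            outcome[i] = "false_alarm" if licked else "correct_rejection"
        premature[i] = licked and in_win[0] < PREMATURE_S
    out = trials.select(np.arange(len(trials)))
    out.outcome = outcome
    out.premature = premature
    return out


def dprime(n_hit: int, n_stim: int, n_fa: int, n_catch: int,
           loglinear: bool = True) -> float:
    """Signal-detection sensitivity Z(hit rate) − Z(FA rate).

    With ``loglinear=True`` (the default, applied systematically) the
    rates are (n_hit + 0.5)/(n_stim + 1) and (n_fa + 0.5)/(n_catch + 1),
    which keeps d' finite even at 0% or 100% rates.
    """
    if n_stim < 1 or n_catch < 1:
        raise ValueError("n_stim and n_catch must be >= 1")
    if not (0 <= n_hit <= n_stim and 0 <= n_fa <= n_catch):
        raise ValueError("counts inconsistent with trial totals")
    if loglinear:
        hr = (n_hit + 0.5) / (n_stim + 1.0)
        fr = (n_fa + 0.5) / (n_catch + 1.0)
    else:
        hr = n_hit / n_stim
        fr = n_fa / n_catch
        if not (0.0 < hr < 1.0 and 0.0 < fr < 1.0):
            raise ValueError("rate of 0 or 1 gives infinite d' without "
                             "the loglinear correction")
    return float(stats.inverse_normal_cdf(hr) - stats.inverse_normal_cdf(fr))


def session_performance(trials: TrialTable, day_index: int = 0,
                        light: str | None = None) -> SessionPerformance:
    """Hit/FA rates and loglinear d' over the non-aborted trials.

    Premature hits count toward the hit rate (the premature exclusion
    applies only to evoked-response averaging).  ``light`` restricts to
    the ``"on"`` or ``"off"`` subset of trials when given.
    """
    keep = trials.outcome != "aborted"
    if light == "on":
        keep &= trials.light_on
    elif light == "off":
        keep &= ~trials.light_on
    elif light is not None:
        raise ValueError("light must be None, 'on' or 'off'")
    sub = trials.select(keep)
    if len(sub) == 0:
        raise ValueError("no non-aborted trials to score")
    n_stim = int(np.sum(sub.kind == "stimulus"))
    n_catch = int(np.sum(sub.kind == "catch"))
    if n_catch == 0:
        raise ValueError("session has no catch trials; FA rate undefined")
    if n_stim == 0:
        raise ValueError("session has no stimulus trials; hit rate undefined")
    n_hit = int(np.sum(sub.outcome == "hit"))
    n_fa = int(np.sum(sub.outcome == "false_alarm"))
    return SessionPerformance(
        n_stim=n_stim, n_catch=n_catch, n_hit=n_hit, n_fa=n_fa,
        hit_rate=n_hit / n_stim, fa_rate=n_fa / n_catch,
        dprime=dprime(n_hit, n_stim, n_fa, n_catch), day_index=day_index)


def select_trained_sessions(perf_by_day: list) -> list:
    """Day indices of the first 3 days with day index > 4 and d' > 1.

    If fewer than 3 days qualify, the qualifying ones are returned with
    a warning.  Input must be sorted by day.
    """
    if not perf_by_day:
        raise ValueError("empty performance list")
    chosen = [p.day_index for p in perf_by_day
              if p.day_index > 4 and p.dprime > 1.0][:3]
    if len(chosen) < 3:
        warnings.warn(f"only {len(chosen)} session(s) satisfy the trained-day "
                      "criteria (day > 4 and d' > 1)", stacklevel=2)
    return chosen


def select_exposed_sessions(n_days: int) -> list:
    """The last 3 day indices of a neutral-exposure series."""
    if n_days < 3:
        raise ValueError("need at least 3 exposure days")
    return [n_days - 2, n_days - 1, n_days]


def performance_table(perfs: dict) -> pd.DataFrame:
    """Cohort summary: one row per (mouse, day) with a selected flag.

    ``perfs`` maps mouse_id → list of SessionPerformance sorted by day.
    """
    rows = []
    for mouse, plist in perfs.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = set(select_trained_sessions(plist))
        for p in plist:
            rows.append({"mouse": mouse, "day": p.day_index,
                         "n_stim": p.n_stim, "n_catch": p.n_catch,
                         "hit_rate": p.hit_rate, "fa_rate": p.fa_rate,
                         "dprime": p.dprime,
                         "selected": p.day_index in selected})
    return pd.DataFrame(rows)
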