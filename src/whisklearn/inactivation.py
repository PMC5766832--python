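"""Behavioral quantification of optogenetic and muscimol inactivation.

Optogenetic sessions interleave light-on trials (30% of stimulus and
catch trials) with light-off trials; per-mouse hit and false-alarm
rates for the two trial classes are compared with the paired Wilcoxon
signed-rank test.  Muscimol sessions are scored in a 5 min block
starting 30 min after the injection and compared, area by area,
against a pooled Ringer's-injection control group with the
Mann-Whitney test under Bonferroni-Holm correction across areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import stats
from .data_model import TrialTable

__all__ = ["InactivationSummary", "split_light_trials", "opto_compare",
           "extract_muscimol_block", "muscimol_compare"]

MUSCIMOL_BLOCK_START_S = 1800.0
MUSCIMOL_BLOCK_DUR_S = 300.0


@dataclass
class InactivationSummary:
    area: str
    condition: str
    hit_rates: np.ndarray
    fa_rates: np.ndarray
    p_hit: float
    p_fa: float


def split_light_trials(trials: TrialTable):
    """Partition a session into (light-on, light-off) trial tables.

    The partition is exhaustive and disjoint; a warning is emitted if
    either class is empty.
    """
    on = trials.select(trials.light_on)
    off = trials.select(~trials.light_on)
    if len(on) == 0 or len(off) == 0:
        warnings.warn("light split produced an empty class", stacklevel=2)
    return on, off


def opto_compare(hit_on, hit_off, fa_on, fa_off):
    """Paired Wilcoxon tests of light-on vs light-off rates.

    All four arrays are per-mouse rates in matched order.  Returns
    ``(p_hit, p_fa)``.
    """
    hit_on, hit_off = np.asarray(hit_on, float), np.asarray(hit_off, float)
    fa_on, fa_off = np.asarray(fa_on, float), np.asarray(fa_off, float)
    if not (len(hit_on) == len(hit_off) == len(fa_on) == len(fa_off)):
        raise ValueError("per-mouse rates must be paired (equal lengths)")
    if len(hit_on) < 5:
        raise ValueError("need at least 5 mice for the paired signed-rank "
                         "test to reach significance")
    return (stats.wilcoxon_signed_rank(hit_on, hit_off),
            stats.wilcoxon_signed_rank(fa_on, fa_off))


def extract_muscimol_block(trials: TrialTable,
                           start_s: float = MUSCIMOL_BLOCK_START_S,
                           dur_s: float = MUSCIMOL_BLOCK_DUR_S) -> TrialTable:
    """Trials with onset in ``[start, start + dur)`` on the session
    clock (anchored to the end of the injection)."""
    mask = (trials.onset_s >= start_s) & (trials.onset_s < start_s + dur_s)
    if not mask.any():
        raise ValueError(
            f"no trials in the muscimol scoring block "
            f"[{start_s}, {start_s + dur_s}) s out of {len(trials)} trials")
    return trials.select(mask)


def muscimol_compare(treated_by_area: dict, control_rates) -> dict:
    """Mann-Whitney per area against the pooled Ringer control group,
    with Bonferroni-Holm adjustment across the tested areas.

    ``treated_by_area`` maps area → per-mouse hit rates; returns
    area → (raw p, adjusted p).
    """
    control = np.asarray(control_rates, dtype=float)
    if len(control) < 3:
        raise ValueError("control group needs at least 3 mice")
    areas = list(treated_by_area)
    raw = []
    for a in areas:
        treated = np.asarray(treated_by_area[a], dtype=float)
        if len(treated) < 3:
            raise ValueError(f"treated group for {a} needs at least 3 mice")
        raw.append(stats.mann_whitney(treated, control))
    adj = stats.holm_adjust(raw)
    return {a: (raw[i], float(adj[i])) for i, a in enumerate(areas)}
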