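"""Session data model: trial tables, continuous LFP, spike units, metadata.

A recording session is the unit of analysis: one mouse, one day, one
behavioral paradigm.  It bundles a trial table (stimulus/catch trials
with lick times and outcomes), a multi-channel continuous LFP recording
with a channel→cortical-area map, per-unit spike trains with mean
waveforms, and session metadata.  Sessions round-trip through a single
HDF5 container; the trial table is additionally mirrored as CSV for
human inspection.

Time conventions
----------------
Trial onsets (``onset_s``) are seconds on the session clock; all
within-trial times (licks, rewards) are seconds relative to the trial
onset.  For catch trials the onset is the scheduled virtual onset, so
catch epochs are extractable exactly like stimulus epochs.  All windows
throughout the package are half-open ``[a, b)``.  LFP is in microvolts,
with negative deflections corresponding to depolarizing-compatible
evoked responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "AREAS",
    "TrialTable",
    "ContinuousRecording",
    "SessionMeta",
    "UnitData",
    "ValidationError",
    "FormatError",
    "write_session",
    "read_session",
]

#: Cortical areas recorded in the six-site preparation, in the
#: canonical sensory-to-frontal order.
AREAS = ("wS1", "wS2", "wM1", "PtA", "dCA1", "mPFC")

TRIAL_KINDS = ("stimulus", "catch")
OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection", "aborted", "unclassified")
PARADIGMS = ("detection", "neutral_exposure")
MANIPULATIONS = ("none", "opto", "muscimol", "ringer")

#: Inter-trial interval bounds (s) enforced on non-aborted schedules.
ITI_MIN_S = 6.0
ITI_MAX_S = 12.0


class ValidationError(ValueError):
    """An invariant of the data model is violated; message names the field."""


class FormatError(IOError):
    """A session container does not conform to the documented layout."""


# ---------------------------------------------------------------------------
# Trial table
# ---------------------------------------------------------------------------

@dataclass
class TrialTable:
    """Per-session record of trial types, times, licks and outcomes.

    Lick times are stored per trial, in seconds relative to the trial
    onset, and may be negative (licks in the preceding no-lick window,
    relevant for aborted trials).
    """

    trial_id: np.ndarray
    kind: np.ndarray
    onset_s: np.ndarray
    lick_times_s: list
    outcome: np.ndarray
    premature: np.ndarray
    light_on: np.ndarray
    reward_s: np.ndarray  # NaN where no reward

    def __post_init__(self):
        self.trial_id = np.asarray(self.trial_id, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype=object)
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.lick_times_s = [np.asarray(l, dtype=float) for l in self.lick_times_s]
        self.outcome = np.asarray(self.outcome, dtype=object)
        self.premature = np.asarray(self.premature, dtype=bool)
        self.light_on = np.asarray(self.light_on, dtype=bool)
        self.reward_s = np.asarray(self.reward_s, dtype=float)

    @classmethod
    def empty(cls) -> "TrialTable":
        return cls(np.empty(0, np.int64), np.empty(0, object), np.empty(0),
                   [], np.empty(0, object), np.empty(0, bool),
                   np.empty(0, bool), np.empty(0))

    def __len__(self) -> int:
        return len(self.trial_id)

    @property
    def first_lick_s(self) -> np.ndarray:
        """First lick time per trial (NaN if no lick)."""
        return np.array([l[0] if len(l) else np.nan for l in self.lick_times_s])

    def select(self, mask) -> "TrialTable":
        """Row subset preserving all fields."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrialTable(
            self.trial_id[idx], self.kind[idx], self.onset_s[idx],
            [self.lick_times_s[i] for i in idx], self.outcome[idx],
            self.premature[idx], self.light_on[idx], self.reward_s[idx])

    def validate(self) -> None:
        n = len(self)
        for name in ("kind", "lick_times_s", "outcome", "premature",
                     "light_on", "reward_s"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name}: length mismatch with trial_id")
        bad = set(self.kind) - set(TRIAL_KINDS)
        if bad:
            raise ValidationError(f"kind: unknown values {sorted(bad)}")
        bad = set(self.outcome) - set(OUTCOMES)
        if bad:
            raise ValidationError(f"outcome: unknown values {sorted(bad)}")
        if n > 1:
            d = np.diff(self.onset_s)
            if np.any(d <= 0):
                raise ValidationError("onset_s: onset times must be strictly increasing")
            if np.any(d < ITI_MIN_S - 1e-9):
                raise ValidationError("onset_s: inter-trial interval below 6 s schedule minimum")
            # The 12 s ceiling holds for schedules without aborted slots;
            # aborted trials may be dropped upstream, stretching gaps.
            if not np.any(self.outcome == "aborted") and np.any(d > ITI_MAX_S + 1e-9):
                raise ValidationError("onset_s: inter-trial interval above 12 s schedule maximum")
        for i in range(n):
            out, kind = self.outcome[i], self.kind[i]
            if kind == "stimulus" and out in ("false_alarm", "correct_rejection"):
                raise ValidationError(f"outcome: {out} on stimulus trial {self.trial_id[i]}")
            if kind == "catch" and out in ("hit", "miss"):
                raise ValidationError(f"outcome: {out} on catch trial {self.trial_id[i]}")
            if self.premature[i]:
                licks = self.lick_times_s[i]
                pos = licks[licks >= 0]
                if len(pos) == 0 or pos[0] >= 0.1:
                    raise ValidationError(
                        f"premature: flagged without a first lick < 0.1 s "
                        f"on trial {self.trial_id[i]}")

    # -- tabular mirrors ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_id": self.trial_id,
            "kind": self.kind.astype(str),
            "onset_s": self.onset_s,
            "outcome": self.outcome.astype(str),
            "premature": self.premature,
            "light_on": self.light_on,
            "first_lick_s": self.first_lick_s,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Continuous recording / metadata / units
# ---------------------------------------------------------------------------

@dataclass
class ContinuousRecording:
    """Multi-channel continuous LFP in microvolts.

    ``samples`` is (n_channels, n_samples); ``channel_area`` maps
    channel index → cortical area; ``t0_s`` is the session-clock time
    of sample 0.
    """

    samples: np.ndarray
    fs_hz: float
    channel_area: dict
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_of(self, area: str) -> int:
        for ch, a in self.channel_area.items():
            if a == area:
                return int(ch)
        raise KeyError(f"no channel mapped to area {area!r}")

    @property
    def areas(self) -> list:
        return [self.channel_area[ch] for ch in sorted(self.channel_area)]

    def validate(self) -> None:
        if not self.fs_hz > 0:
            raise ValidationError("fs_hz: must be positive")
        if self.samples.ndim != 2:
            raise ValidationError("samples: must be a 2-D channel x time array")
        areas = list(self.channel_area.values())
        if len(set(areas)) != len(areas):
            raise ValidationError("channel_area: mapped areas must be unique")
        for ch in self.channel_area:
            if not 0 <= int(ch) < self.samples.shape[0]:
                raise ValidationError(f"channel_area: channel {ch} out of range")


@dataclass
class SessionMeta:
    mouse_id: str
    day_index: int
    paradigm: str = "detection"
    manipulation: str = "none"
    target_area: str | None = None

    def validate(self) -> None:
        if self.day_index < 1:
            raise ValidationError("day_index: must be >= 1")
        if self.paradigm not in PARADIGMS:
            raise ValidationError(f"paradigm: unknown value {self.paradigm!r}")
        if self.manipulation not in MANIPULATIONS:
            raise ValidationError(f"manipulation: unknown value {self.manipulation!r}")
        if self.target_area is not None and self.target_area not in AREAS:
            raise ValidationError(f"target_area: unknown area {self.target_area!r}")


@dataclass
class UnitData:
    """A sorted single unit: spike times on the session clock plus its
    mean waveform and trough-to-peak duration used for RSU/FSU
    classification."""

    unit_id: str
    spike_times_s: np.ndarray
    waveform: np.ndarray = field(default_factory=lambda: np.zeros(0))
    waveform_fs_hz: float = 30000.0
    trough_to_peak_ms: float = 0.5
    area: str = "mPFC"

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.waveform = np.asarray(self.waveform, dtype=float)

    def validate(self) -> None:
        if len(self.spike_times_s):
            if np.any(np.diff(self.spike_times_s) < 0):
                raise ValidationError(f"spike_times_s: not sorted for unit {self.unit_id}")
            if self.spike_times_s[0] < 0:
                raise ValidationError(f"spike_times_s: negative time for unit {self.unit_id}")
        if not self.trough_to_peak_ms > 0:
            raise ValidationError(f"trough_to_peak_ms: must be > 0 for unit {self.unit_id}")
        if self.area not in AREAS:
            raise ValidationError(f"area: unknown area {self.area!r}")


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------
# Layout: /meta (JSON attribute block), /trials (column datasets, ragged
# lick times as flat values + row offsets), /lfp (samples, fs, t0,
# channel_area as JSON), /units/<unit_id> (spike_times_s, waveform).

def write_session(meta: SessionMeta, trials: TrialTable,
                  lfp: ContinuousRecording, units: list,
                  path, csv_mirror: bool = True) -> None:
    """Write one session bundle to an HDF5 container.

    All invariants are validated first.  When ``csv_mirror`` is true a
    sibling ``<stem>.trials.csv`` is written next to the container.
    """
    meta.validate()
    trials.validate()
    lfp.validate()
    for u in units:
        u.validate()

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["meta_json"] = json.dumps({
            "mouse_id": meta.mouse_id, "day_index": meta.day_index,
            "paradigm": meta.paradigm, "manipulation": meta.manipulation,
            "target_area": meta.target_area})

        g = f.create_group("trials")
        g.create_dataset("trial_id", data=trials.trial_id)
        g.create_dataset("kind", data=np.array(trials.kind, dtype="S16"))
        g.create_dataset("onset_s", data=trials.onset_s)
        g.create_dataset("outcome", data=np.array(trials.outcome, dtype="S24"))
        g.create_dataset("premature", data=trials.premature)
        g.create_dataset("light_on", data=trials.light_on)
        g.create_dataset("reward_s", data=trials.reward_s)
        flat = (np.concatenate(trials.lick_times_s)
                if trials.lick_times_s else np.zeros(0))
        offsets = np.cumsum([0] + [len(l) for l in trials.lick_times_s])
        g.create_dataset("lick_flat", data=flat)
        g.create_dataset("lick_offsets", data=offsets)

        g = f.create_group("lfp")
        g.create_dataset("samples", data=lfp.samples.astype(np.float32),
                         compression="gzip", compression_opts=1)
        g.attrs["fs_hz"] = float(lfp.fs_hz)
        g.attrs["t0_s"] = float(lfp.t0_s)
        g.attrs["channel_area_json"] = json.dumps(
            {str(ch): a for ch, a in lfp.channel_area.items()})

        g = f.create_group("units")
        for u in units:
            ug = g.create_group(u.unit_id)
            ug.create_dataset("spike_times_s", data=u.spike_times_s)
            ug.create_dataset("waveform", data=u.waveform)
            ug.attrs["waveform_fs_hz"] = float(u.waveform_fs_hz)
            ug.attrs["trough_to_peak_ms"] = float(u.trough_to_peak_ms)
            ug.attrs["area"] = u.area

    if csv_mirror:
        trials.to_csv(path.with_suffix(".trials.csv"))


def read_session(path):
    """Read a session container; returns (meta, trials, lfp, units).

    All invariants are re-validated on load; structural problems raise
    :class:`FormatError`.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "meta_json" not in f.attrs:
            raise FormatError("missing meta_json attribute")
        m = json.loads(f.attrs["meta_json"])
        meta = SessionMeta(mouse_id=m["mouse_id"], day_index=int(m["day_index"]),
                           paradigm=m["paradigm"], manipulation=m["manipulation"],
                           target_area=m["target_area"])
        for group in ("trials", "lfp", "units"):
            if group not in f:
                raise FormatError(f"missing group /{group}")

        g = f["trials"]
        try:
            flat = g["lick_flat"][...]
            offsets = g["lick_offsets"][...]
            licks = [flat[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)]
            trials = TrialTable(
                g["trial_id"][...],
                np.array([s.decode() for s in g["kind"][...]], dtype=object),
                g["onset_s"][...], licks,
                np.array([s.decode() for s in g["outcome"][...]], dtype=object),
                g["premature"][...], g["light_on"][...], g["reward_s"][...])
        except KeyError as e:
            raise FormatError(f"trials group missing dataset: {e}") from e

        g = f["lfp"]
        if "channel_area_json" not in g.attrs:
            raise FormatError("lfp group missing channel_area map")
        try:
            lfp = ContinuousRecording(
                samples=g["samples"][...].astype(float),
                fs_hz=float(g.attrs["fs_hz"]),
                channel_area={int(ch): a for ch, a in
                              json.loads(g.attrs["channel_area_json"]).items()},
                t0_s=float(g.attrs["t0_s"]))
        except KeyError as e:
            raise FormatError(f"lfp group missing dataset: {e}") from e

        units = []
        for uid in sorted(f["units"]):
            ug = f["units"][uid]
            units.append(UnitData(
                unit_id=uid, spike_times_s=ug["spike_times_s"][...],
                waveform=ug["waveform"][...],
                waveform_fs_hz=float(ug.attrs["waveform_fs_hz"]),
                trough_to_peak_ms=float(ug.attrs["trough_to_peak_ms"]),
                area=ug.attrs["area"]))

    meta.validate()
    trials.validate()
    lfp.validate()
    for u in units:
        u.validate()
    return meta, trials, lfp, units
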