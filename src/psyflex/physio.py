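"""Trial-level fear-response extraction from physiological traces.

Works identically for skin conductance (SCR) and pupillometry: the trial
response is the *peak change* — the maximum of the trace in an 8-second
window following CS offset, relative to a baseline value read 500 ms before
stimulus onset. The baseline is a single linearly interpolated sample by
default; a short mean window is available behind a flag. The peak is the
signed maximum change (anticipatory arousal is positive-going in both
channels); no channel transformation is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError

RESPONSE_WINDOW_S = 8.0
BASELINE_OFFSET_S = 0.5


@dataclass
class PhysioTrace:
    """One subject's continuous recording plus its trial event table.

    Attributes
    ----------
    channel : "scr" or "pupil".
    sampling_rate : Hz.
    samples : 1-D array in channel units, sampled at ``sampling_rate``
        starting at t = 0.
    events : DataFrame with columns ``trial``, ``onset``, ``offset``
        (seconds, stimulus onset and CS offset per trial).
    """

    channel: str
    sampling_rate: float
    samples: np.ndarray
    events: pd.DataFrame
    subject: str | int | None = field(default=None)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise StructuralError("sampling_rate must be positive")
        need = {"trial", "onset", "offset"}
        if not need <= set(self.events.columns):
            raise StructuralError(f"event table needs columns {sorted(need)}")
        onsets = self.events["onset"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            raise StructuralError("event onset times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) / self.sampling_rate


@dataclass(frozen=True)
class TrialResponse:
    subject: str | int | None
    trial: int
    channel: str
    response: float  # windowed max − baseline, channel units
    baseline: float
    usable: bool
    reason: str = ""


def extract_trial_response(
    trace: PhysioTrace,
    trial: int,
    window_s: float = RESPONSE_WINDOW_S,
    baseline_offset_s: float = BASELINE_OFFSET_S,
    baseline_mode: str = "point",
    baseline_window_s: float = 0.5,
) -> TrialResponse:
    """Extract one trial's peak-change response.

    baseline_mode "point" (default) reads a single interpolated value at
    onset − ``baseline_offset_s``; "window" averages the
    ``baseline_window_s`` seconds ending there. The response window is
    (offset, offset + ``window_s``]. Truncated windows or non-finite samples
    make the trial unusable (flagged with a reason, never raised).
    """
    row = trace.events.loc[trace.events["trial"] == trial]
    if row.empty:
        raise StructuralError(f"trial {trial} not in event table")
    onset = float(row["onset"].iloc[0])
    offset = float(row["offset"].iloc[0])
    t = trace.times
    t_base = onset - baseline_offset_s

    def unusable(reason: str) -> TrialResponse:
        return TrialResponse(trace.subject, trial, trace.channel, np.nan, np.nan, False, reason)

    if t_base < 0:
        return unusable("baseline before trace start")
    if offset + window_s > trace.duration + 1e-9:
        return unusable("truncated window")
    if baseline_mode == "point":
        baseline = float(np.interp(t_base, t, trace.samples))
    elif baseline_mode == "window":
        m = (t >= t_base - baseline_window_s) & (t <= t_base)
        baseline = float(np.mean(trace.samples[m]))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    in_window = (t > offset) & (t <= offset + window_s + 1e-9)
    seg = trace.samples[in_window]
    if len(seg) == 0:
        return unusable("empty window")
    if not np.all(np.isfinite(seg)) or not np.isfinite(baseline):
        return unusable("non-finite samples in window")
    return TrialResponse(
        trace.subject, trial, trace.channel, float(seg.max() - baseline), baseline, True
    )


def extract_all(trace: PhysioTrace, **kwargs) -> pd.DataFrame:
    """Extract every trial in the event table; returns a tidy DataFrame."""
    rows = [
        extract_trial_response(trace, int(tr), **kwargs) for tr in trace.events["trial"]
    ]
    return pd.DataFrame(
        {
            "subject": [r.subject for r in rows],
            "trial": [r.trial for r in rows],
            "channel": [r.channel for r in rows],
            "response": [r.response for r in rows],
            "baseline": [r.baseline for r in rows],
            "usable": [r.usable for r in rows],
            "reason": [r.reason for r in rows],
        }
    )


@dataclass
class ScreenReport:
    """Outcome of subject-level usability screening."""

    usable_subjects: list
    excluded: pd.DataFrame  # subject, reason
    counts: dict  # per-channel usable subject counts

    def summary(self) -> str:
        lines = [f"usable subjects per channel: {self.counts}"]
        for _, r in self.excluded.iterrows():
            lines.append(f"  excluded {r['subject']} ({r['channel']}): {r['reason']}")
        return "\n".join(lines)


def screen_subjects(
    responses: pd.DataFrame,
    sd_floor: float = 1e-3,
    min_usable_fraction: float = 0.75,
) -> ScreenReport:
    """Flag non-responders and incomplete subjects.

    A subject is excluded on a channel when the SD of their usable responses
    is below ``sd_floor`` (physiological non-responder, e.g. no measurable
    skin conductance) or fewer than ``min_usable_fraction`` of trials are
    usable. Expects the tidy frame from :func:`extract_all`, with multiple
    subjects/channels concatenated.
    """
    need = {"subject", "channel", "response", "usable"}
    if not need <= set(responses.columns):
        raise StructuralError(f"responses table needs columns {sorted(need)}")
    usable, excluded, counts = [], [], {}
    for (sid, ch), grp in responses.groupby(["subject", "channel"], sort=True):
        frac = grp["usable"].mean()
        vals = grp.loc[grp["usable"], "response"]
        if frac < min_usable_fraction:
            excluded.append({"subject": sid, "channel": ch, "reason": f"only {frac:.0%} trials usable"})
            continue
        if len(vals) == 0 or float(np.std(vals)) < sd_floor:
            excluded.append({"subject": sid, "channel": ch, "reason": "non-responder (flat responses)"})
            continue
        usable.append((sid, ch))
        counts[ch] = counts.get(ch, 0) + 1
    return ScreenReport(
        usable_subjects=usable,
        excluded=pd.DataFrame(excluded, columns=["subject", "channel", "reason"]),
        counts=counts,
    )
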