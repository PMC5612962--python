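"""Multi-pass threshold detection of calcium transients.

The signal is first mapped onto [0, 1] with a global min-max normalisation.
The detector then sweeps a series of descending threshold passes (step 0.1
from just below 1 down to an amplitude floor of 0.2). At each pass level it
segments the samples at or above the level; each segment is extended on both
sides down to the nearest strict local minimum and becomes an event when its
extent satisfies the duration bounds (0.5-6 s) and does not overlap a
previously accepted event. Searching the highest levels first means large
transients claim their extent before lower passes see the residue. Event
amplitude is measured vertically, from the lowest point of the extended
extent to the highest point of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Hypnogram, ValidationError

__all__ = [
    "TransientConfig",
    "TransientSet",
    "normalize_signal",
    "detect_transients",
    "transient_statistics",
]


@dataclass
class TransientConfig:
    pass_step: float = 0.1
    floor_threshold: float = 0.2
    min_dur_s: float = 0.5
    max_dur_s: float = 6.0

    def __post_init__(self):
        if not 0 < self.floor_threshold < 1:
            raise ValidationError("floor_threshold must be in (0, 1)")
        if not 0 < self.pass_step <= self.floor_threshold:
            raise ValidationError("need 0 < pass_step <= floor_threshold")
        if not 0 < self.min_dur_s <= self.max_dur_s:
            raise ValidationError("need 0 < min_dur_s <= max_dur_s")

    @property
    def pass_levels(self) -> np.ndarray:
        """Descending pass levels from 1 - step down to the floor."""
        n = int(np.floor((1.0 - self.floor_threshold) / self.pass_step + 1e-9))
        levels = 1.0 - self.pass_step * np.arange(1, n + 1)
        return np.round(levels, 12)


@dataclass
class TransientSet:
    """Detected events: onset_s, offset_s, duration_s, amplitude, pass_level.

    Intervals are half-open, sorted and non-overlapping; amplitudes are in
    normalised [0, 1] units.
    """

    events: pd.DataFrame
    rate: float

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return self.events["onset_s"].to_numpy()

    @property
    def offsets(self) -> np.ndarray:
        return self.events["offset_s"].to_numpy()

    @property
    def amplitudes(self) -> np.ndarray:
        return self.events["amplitude"].to_numpy()


_EVENT_COLUMNS = ["onset_s", "offset_s", "duration_s", "amplitude", "pass_level"]


def normalize_signal(x) -> np.ndarray:
    """Affine map of a trace onto [0, 1]: (x - min) / (max - min)."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty input")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValidationError("constant input cannot be normalised")
    return (arr - lo) / (hi - lo)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(mask)]))
    return list(zip(starts.tolist(), ends.tolist()))


def _extend_to_minimum(x: np.ndarray, a: int, b: int) -> tuple[int, int]:
    """Walk outward from segment [a, b) to the nearest strict local minima."""
    left = a
    while left > 0 and x[left - 1] < x[left]:
        left -= 1
    right = b - 1
    while right < len(x) - 1 and x[right + 1] < x[right]:
        right += 1
    return left, right


def detect_transients(
    x_norm, rate: float, cfg: TransientConfig | None = None
) -> TransientSet:
    """Multi-pass threshold detection on a [0, 1]-normalised trace.

    See the module docstring for the pass semantics. Events touching either
    trace boundary are discarded (their duration is ambiguous).
    """
    cfg = cfg or TransientConfig()
    x = np.asarray(x_norm, dtype=float)
    if x.size == 0:
        raise ValidationError("empty input")
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValidationError("input must be normalised to [0, 1]")
    n = len(x)
    occupied = np.zeros(n, dtype=bool)
    rows = []
    for level in cfg.pass_levels:
        for a, b in _runs_above(x >= level - 1e-12):
            left, right = _extend_to_minimum(x, a, b)
            if left == 0 or right == n - 1:
                continue  # touches the trace boundary
            dur = (right - left) / rate
            if not cfg.min_dur_s <= dur <= cfg.max_dur_s:
                continue
            # interior overlap test lets adjacent events share a boundary
            # minimum sample without counting as overlapping
            if occupied[left + 1 : right].any():
                continue
            amp = float(x[a:b].max() - x[left : right + 1].min())
            occupied[left + 1 : right] = True
            rows.append(
                {
                    "onset_s": left / rate,
                    "offset_s": right / rate,
                    "duration_s": dur,
                    "amplitude": amp,
                    "pass_level": float(level),
                }
            )
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df = df.sort_values("onset_s", ignore_index=True)
    return TransientSet(events=df, rate=rate)


def transient_statistics(
    ts: TransientSet, h: Hypnogram
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-state transient frequency (events/min) and amplitudes.

    An event belongs to the state of the epoch containing its onset;
    frequency divides the count by the state's total time in minutes.
    Returns a summary frame indexed by state plus per-state amplitude
    arrays for distribution comparisons.
    """
    labels = np.asarray(h.labels)
    if len(ts) and ts.offsets.max() > h.duration_s + 1e-9:
        raise ValidationError("events extend beyond the hypnogram")
    states = [s for s in ("AW", "QW", "NREM", "IS", "REM") if (labels == s).any()]
    if len(ts):
        ev_state = labels[
            np.minimum(
                (ts.onsets / h.epoch_length_s).astype(int), h.n_epochs - 1
            )
        ]
    else:
        ev_state = np.empty(0, dtype=labels.dtype)
    rows = []
    amplitudes: dict[str, np.ndarray] = {}
    for s in states:
        minutes = (labels == s).sum() * h.epoch_length_s / 60.0
        sel = ev_state == s
        amplitudes[s] = ts.amplitudes[sel] if len(ts) else np.empty(0)
        rows.append(
            {
                "state": s,
                "n_events": int(sel.sum()),
                "minutes": minutes,
                "rate_per_min": sel.sum() / minutes if minutes > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("state"), amplitudes
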