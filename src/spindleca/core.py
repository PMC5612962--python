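"""Core containers for polysomnographic and optical recordings.

Everything downstream works on a handful of small, validated containers:
multichannel signals (:class:`TimeSeries`), 4-s epoch vigilance-state
sequences (:class:`Hypnogram`), named frequency bands (:class:`BandScheme`),
manually annotated spindle intervals (:class:`SpindleAnnotations`),
juxtacellular spike times (:class:`SpikeTrain`) and two-photon ROI
fluorescence matrices (:class:`ROIMatrix`).

Conventions: time in seconds, rates in Hz, epoch indices 0-based, intervals
half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STATES",
    "WAKE_STATES",
    "SWS_STATES",
    "DEFAULT_EEG_BANDS",
    "SCORING_BANDS",
    "CA_BAND",
    "FormatError",
    "ValidationError",
    "TimeSeries",
    "Hypnogram",
    "BandScheme",
    "SpindleAnnotations",
    "SpikeTrain",
    "ROIMatrix",
    "slice_epochs",
    "pool_state",
]

#: Closed set of per-epoch vigilance-state labels. ART marks artefact epochs,
#: which are excluded from every downstream computation.
STATES = ("AW", "QW", "NREM", "IS", "REM", "ART")

WAKE_STATES = frozenset({"AW", "QW"})
SWS_STATES = frozenset({"NREM", "IS"})

#: EEG band scheme used throughout: slow oscillation, delta, theta, sigma
#: (the spindle band), beta and the two gamma bands.
DEFAULT_EEG_BANDS = {
    "so": (0.5, 1.5),
    "delta": (1.0, 4.0),
    "theta": (5.0, 9.0),
    "sigma": (9.0, 16.0),
    "beta": (16.0, 30.0),
    "slow_gamma": (30.0, 50.0),
    "fast_gamma": (60.0, 100.0),
}

#: Bands used by the rule-based scorer: slow-wave activity, theta, sigma.
SCORING_BANDS = {"swa": (0.5, 4.0), "theta": (5.0, 9.0), "sigma": (9.0, 16.0)}

#: Band used for the optical calcium channel (slow population oscillation).
CA_BAND = (0.1, 1.0)


class FormatError(ValueError):
    """A file or buffer does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


def _as_2d(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValidationError(f"data must be 1-D or 2-D, got ndim={arr.ndim}")
    return arr


@dataclass
class TimeSeries:
    """Multichannel signal sampled at a single rate.

    ``data`` is an ``(n_channels, n_samples)`` float array; ``labels`` names
    the channels (e.g. ``EEG-FF``, ``EEG-FP``, ``EMG``, ``CA``).
    """

    data: np.ndarray
    rate: float
    labels: Sequence[str]
    units: Sequence[str] | None = None
    t0: float = 0.0

    def __post_init__(self):
        self.data = _as_2d(self.data)
        if self.rate <= 0:
            raise ValidationError("sampling rate must be > 0")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.units is None:
            self.units = [""] * len(self.labels)
        self.units = list(self.units)
        if len(self.units) != len(self.labels):
            raise ValidationError("units must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array (view)."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.labels}") from None
        return self.data[idx]


@dataclass
class Hypnogram:
    """Sequence of per-epoch vigilance-state labels (default 4-s epochs)."""

    labels: np.ndarray
    epoch_length_s: float = 4.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="U4")
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be > 0")
        bad = ~np.isin(self.labels, STATES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"unknown state label {self.labels[i]!r} at epoch {i}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def runs(self) -> list[tuple[str, int, int]]:
        """Maximal same-state runs as ``(state, start, end)`` (end exclusive)."""
        out: list[tuple[str, int, int]] = []
        if self.n_epochs == 0:
            return out
        change = np.flatnonzero(self.labels[1:] != self.labels[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [self.n_epochs]))
        for s, e in zip(starts, ends):
            out.append((str(self.labels[s]), int(s), int(e)))
        return out

    def mask(self, states: Iterable[str]) -> np.ndarray:
        """Boolean per-epoch mask for membership in ``states``."""
        return np.isin(self.labels, list(states))

    def epoch_of_time(self, t: float) -> int:
        return int(t // self.epoch_length_s)

    def state_of_time(self, t: float) -> str:
        i = self.epoch_of_time(t)
        if not 0 <= i < self.n_epochs:
            raise ValidationError(f"time {t} s outside hypnogram")
        return str(self.labels[i])


class BandScheme(dict):
    """Named frequency bands, ``name -> (lo_hz, hi_hz)`` with ``lo < hi``."""

    def __init__(self, bands: Mapping[str, tuple[float, float]]):
        super().__init__()
        for name, (lo, hi) in bands.items():
            lo, hi = float(lo), float(hi)
            if not lo < hi:
                raise ValidationError(f"band {name!r}: need lo < hi, got [{lo}, {hi}]")
            self[name] = (lo, hi)

    def bin_mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        """Boolean mask of frequency bins belonging to band ``name``.

        Bins are included when ``lo <= f <= hi``; a bin that sits exactly on
        a shared edge (this band's ``lo`` equals another band's ``hi``) is
        assigned to the lower band only.
        """
        lo, hi = self[name]
        mask = (freqs >= lo) & (freqs <= hi)
        if any(abs(other_hi - lo) < 1e-12 for n, (_, other_hi) in self.items() if n != name):
            mask &= freqs > lo
        return mask


def _check_intervals(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if arr.size and not (arr[:, 0] < arr[:, 1]).all():
        raise ValidationError("each interval needs onset < offset")
    if arr.size and not (np.diff(arr[:, 0]) >= 0).all():
        raise ValidationError("intervals must be sorted by onset")
    if len(arr) > 1 and (arr[1:, 0] < arr[:-1, 1]).any():
        raise ValidationError("intervals must not overlap")
    return arr


@dataclass
class SpindleAnnotations:
    """Sorted, non-overlapping spindle intervals ``(onset_s, offset_s)``."""

    intervals: np.ndarray

    def __post_init__(self):
        self.intervals = _check_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def onsets(self) -> np.ndarray:
        return self.intervals[:, 0] if len(self) else np.empty(0)

    @property
    def offsets(self) -> np.ndarray:
        return self.intervals[:, 1] if len(self) else np.empty(0)

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    def density(self, start_s: float, stop_s: float) -> float:
        """Cumulative spindle seconds inside ``[start_s, stop_s)``."""
        if not len(self):
            return 0.0
        lo = np.maximum(self.onsets, start_s)
        hi = np.minimum(self.offsets, stop_s)
        return float(np.clip(hi - lo, 0.0, None).sum())


@dataclass
class SpikeTrain:
    """Strictly increasing spike times from a juxtacellular recording."""

    times_s: np.ndarray
    acquisition_rate: float = 25000.0

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float).ravel()
        if self.acquisition_rate <= 0:
            raise ValidationError("acquisition_rate must be > 0")
        if self.times_s.size and self.times_s[0] < 0:
            raise ValidationError("spike times must be >= 0")
        if self.times_s.size > 1 and not (np.diff(self.times_s) > 0).all():
            raise ValidationError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class ROIMatrix:
    """Two-photon ROI fluorescence traces, ``(n_rois, n_samples)``."""

    data: np.ndarray
    rate: float
    roi_ids: Sequence[str] | None = None
    is_dff: bool = False

    def __post_init__(self):
        self.data = _as_2d(self.data)
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")
        if self.roi_ids is None:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.data.shape[0])]
        self.roi_ids = list(self.roi_ids)
        if len(self.roi_ids) != self.data.shape[0]:
            raise ValidationError("roi_ids must match row count")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def slice_epochs(ts: TimeSeries, epoch_length_s: float = 4.0) -> np.ndarray:
    """Cut a signal into consecutive fixed-length epochs.

    Returns an ``(n_epochs, n_channels, epoch_samples)`` view; the trailing
    partial epoch is discarded. ``epoch_length_s * rate`` must be a whole
    number of samples.
    """
    m = epoch_length_s * ts.rate
    if abs(m - round(m)) > 1e-9:
        raise ValidationError(
            f"epoch of {epoch_length_s} s is not a whole number of samples at {ts.rate} Hz"
        )
    m = int(round(m))
    if m < 1:
        raise ValidationError("epoch must contain at least one sample")
    n_ep = ts.n_samples // m
    trimmed = ts.data[:, : n_ep * m]
    return np.moveaxis(trimmed.reshape(ts.n_channels, n_ep, m), 0, 1)


def pool_state(label: str) -> str | None:
    """Map a 5-state label onto the pooled WAKE / SWS / REM categories."""
    if label in WAKE_STATES:
        return "WAKE"
    if label in SWS_STATES:
        return "SWS"
    if label == "REM":
        return "REM"
    return None
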