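"""Rule-based vigilance-state scoring and hypnogram episode analysis.

Scoring follows the classical polygraphic rules for rodents: wakefulness
has high/variable EMG, NREM sleep has low EMG with high slow-wave and
sigma activity, REM shows the wake EEG signature (parietal theta) with
muscle atonia, and the intermediate stage (IS) is a run of at least six
4-s epochs with elevated sigma plus parietal theta immediately following
NREM sleep. "High" and "low" are per-recording percentile cut-offs since
the underlying criteria are qualitative.

Episode analysis pools AW+QW into WAKE and NREM+IS into SWS and extracts
behavioural episodes: at least 13 epochs (>= 52 s) of a pooled state, not
interrupted by more than 30% of epochs of any other state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .core import Hypnogram, ValidationError, pool_state

if TYPE_CHECKING:  # pragma: no cover
    from .spectral import BandPowerTable

__all__ = [
    "ScoringThresholds",
    "score_epochs",
    "is_candidates",
    "enforce_is_rule",
    "state_statistics",
    "transition_statistics",
    "Episode",
    "EpisodeSet",
    "detect_episodes",
]


@dataclass
class ScoringThresholds:
    """Percentile cut-offs (0-100, exclusive) defining "high" activity."""

    emg_pct: float = 60.0
    swa_pct: float = 65.0
    sigma_pct: float = 65.0
    theta_pct: float = 65.0

    def __post_init__(self):
        for name in ("emg_pct", "swa_pct", "sigma_pct", "theta_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValidationError(f"{name} must be in (0, 100), got {v}")


def _high(values: np.ndarray, pct: float, ties_high: bool = True) -> np.ndarray:
    """Per-recording "high" flag at a percentile cut-off.

    Ties count as high for EEG band powers but as low for EMG, so a
    degenerate flat recording falls through to the sleep-side rules.
    """
    thr = np.percentile(values, pct)
    return values >= thr if ties_high else values > thr


def score_epochs(
    bp: "BandPowerTable",
    emg_power,
    thr: ScoringThresholds | None = None,
    ff_channel: str = "EEG-FF",
    fp_channel: str = "EEG-FP",
) -> Hypnogram:
    """Score each epoch as AW / QW / NREM / REM from band power and EMG.

    ``bp`` must carry the scoring bands (``swa``, ``theta``, ``sigma``):
    slow-wave and sigma activity are taken from the fronto-frontal EEG and
    theta from the fronto-parietal one. IS is assigned afterwards by
    :func:`enforce_is_rule`. Deterministic given thresholds.
    """
    thr = thr or ScoringThresholds()
    emg = np.asarray(emg_power, float)
    if len(emg) != bp.n_epochs:
        raise ValidationError(
            f"EMG has {len(emg)} epochs, band power {bp.n_epochs}"
        )
    swa = bp.power(ff_channel, "swa").to_numpy()
    sigma = bp.power(ff_channel, "sigma").to_numpy()
    theta = bp.power(fp_channel, "theta").to_numpy()

    emg_hi = _high(emg, thr.emg_pct, ties_high=False)
    swa_hi = _high(swa, thr.swa_pct)
    sigma_hi = _high(sigma, thr.sigma_pct)
    theta_hi = _high(theta, thr.theta_pct)

    labels = np.full(bp.n_epochs, "QW", dtype="U4")
    labels[~emg_hi & (swa_hi | sigma_hi)] = "NREM"
    labels[~emg_hi & ~(swa_hi | sigma_hi) & theta_hi] = "REM"
    labels[emg_hi & theta_hi] = "AW"
    labels[emg_hi & ~theta_hi] = "QW"
    return Hypnogram(labels, epoch_length_s=bp.epoch_length_s)


def is_candidates(
    bp: "BandPowerTable",
    thr: ScoringThresholds | None = None,
    ff_channel: str = "EEG-FF",
    fp_channel: str = "EEG-FP",
) -> np.ndarray:
    """Per-epoch IS candidacy: elevated sigma plus high parietal theta."""
    thr = thr or ScoringThresholds()
    sigma = bp.power(ff_channel, "sigma").to_numpy()
    theta = bp.power(fp_channel, "theta").to_numpy()
    return _high(sigma, thr.sigma_pct) & _high(theta, thr.theta_pct)


def enforce_is_rule(
    h: Hypnogram, candidates, min_epochs: int = 6
) -> Hypnogram:
    """Relabel qualifying candidate runs as IS.

    A maximal run of consecutive candidate epochs becomes IS when it is at
    least ``min_epochs`` long and the epoch immediately preceding the run
    is scored NREM; every other candidate keeps its original label.
    """
    cand = np.asarray(candidates, bool)
    if len(cand) != h.n_epochs:
        raise ValidationError("candidate flags not aligned with hypnogram")
    labels = h.labels.copy()
    i = 0
    n = len(cand)
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j < n and cand[j]:
            j += 1
        if j - i >= min_epochs and i > 0 and labels[i - 1] == "NREM":
            labels[i:j] = "IS"
        i = j
    return Hypnogram(labels, epoch_length_s=h.epoch_length_s)


def state_statistics(h: Hypnogram, min_bout_epochs: int = 5) -> pd.DataFrame:
    """Percentage of time and mean bout duration per vigilance state.

    Percentages are over non-artefact epochs and sum to 100. A bout is a
    maximal same-state run strictly longer than ``min_bout_epochs`` epochs;
    durations are in seconds. States without bouts get NaN.
    """
    if h.n_epochs == 0:
        raise ValidationError("empty hypnogram")
    labels = np.asarray(h.labels)
    good = labels != "ART"
    n_good = int(good.sum())
    if n_good == 0:
        raise ValidationError("hypnogram contains only artefact epochs")
    states = [s for s in ("AW", "QW", "NREM", "IS", "REM") if (labels == s).any()]
    bout_lengths: dict[str, list[int]] = {s: [] for s in states}
    for state, start, end in h.runs():
        if state in bout_lengths and end - start > min_bout_epochs:
            bout_lengths[state].append(end - start)
    rows = []
    for s in states:
        lens = bout_lengths[s]
        rows.append(
            {
                "state": s,
                "percent": 100.0 * (labels == s).sum() / n_good,
                "n_bouts": len(lens),
                "mean_bout_s": (
                    float(np.mean(lens)) * h.epoch_length_s if lens else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("state")


def transition_statistics(h: Hypnogram, from_state: str) -> pd.Series:
    """Distribution (in %) over the states that follow ``from_state`` runs.

    For each maximal run of ``from_state``, the label of the first
    following epoch is tallied (runs ending at the recording edge and
    transitions into artefact are skipped). Percentages sum to 100.
    """
    labels = np.asarray(h.labels)
    if not (labels == from_state).any():
        raise ValidationError(f"state {from_state!r} absent from hypnogram")
    tally: dict[str, int] = {}
    for state, start, end in h.runs():
        if state != from_state or end >= h.n_epochs:
            continue
        nxt = str(labels[end])
        if nxt == "ART":
            continue
        tally[nxt] = tally.get(nxt, 0) + 1
    if not tally:
        raise ValidationError(f"no scorable transitions out of {from_state!r}")
    total = sum(tally.values())
    out = pd.Series({k: 100.0 * v / total for k, v in tally.items()})
    return out.sort_values(ascending=False)


@dataclass
class Episode:
    """One behavioural episode of a pooled state (WAKE / SWS / REM)."""

    state: str
    start_epoch: int
    end_epoch: int  # inclusive, matches the episode state
    member_epochs: np.ndarray = field(repr=False)

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch + 1

    @property
    def interruption_fraction(self) -> float:
        return 1.0 - len(self.member_epochs) / self.n_epochs

    def duration_s(self, epoch_length_s: float = 4.0) -> float:
        return self.n_epochs * epoch_length_s


@dataclass
class EpisodeSet:
    episodes: list[Episode]
    epoch_length_s: float = 4.0

    def __post_init__(self):
        prev_end = -1
        for ep in self.episodes:
            if ep.start_epoch <= prev_end:
                raise ValidationError("episodes must be sorted and non-overlapping")
            prev_end = ep.end_epoch

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    def __getitem__(self, i) -> Episode:
        return self.episodes[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": ep.state,
                "start_s": ep.start_epoch * self.epoch_length_s,
                "end_s": (ep.end_epoch + 1) * self.epoch_length_s,
                "n_epochs": ep.n_epochs,
                "interruption_fraction": ep.interruption_fraction,
            }
            for ep in self.episodes
        ]
        return pd.DataFrame(
            rows,
            columns=["state", "start_s", "end_s", "n_epochs", "interruption_fraction"],
        )


def detect_episodes(
    h: Hypnogram,
    min_epochs: int = 13,
    max_interruption: float = 0.30,
) -> EpisodeSet:
    """Detect behavioural episodes of the pooled WAKE / SWS / REM states.

    Scanning left to right, an episode starting at an epoch of a pooled
    state extends to the furthest epoch of the same pooled state such that
    the fraction of non-matching epochs within the span stays at or below
    ``max_interruption``; spans shorter than ``min_epochs`` are dropped and
    the scan resumes one epoch later. Both span boundaries match the
    episode state by construction, earlier-starting episodes win, and the
    remainder is re-scanned after each accepted episode. Artefact epochs
    never start an episode and count as interruptions inside one.
    """
    pooled = np.array([pool_state(s) or "" for s in h.labels], dtype="U4")
    n = h.n_epochs
    episodes: list[Episode] = []
    i = 0
    while i < n:
        s = pooled[i]
        if not s:
            i += 1
            continue
        match = pooled[i:] == s
        csum = np.cumsum(match)
        span = np.arange(1, n - i + 1)
        valid = match & ((span - csum) <= max_interruption * span)
        if not valid.any():
            i += 1
            continue
        j = i + int(np.flatnonzero(valid)[-1])
        if j - i + 1 < min_epochs:
            i += 1
            continue
        members = i + np.flatnonzero(match[: j - i + 1])
        episodes.append(
            Episode(state=str(s), start_epoch=i, end_epoch=j, member_epochs=members)
        )
        i = j + 1
    return EpisodeSet(episodes, epoch_length_s=h.epoch_length_s)
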