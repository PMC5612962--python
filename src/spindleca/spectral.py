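"""Epoch-wise spectral power and power-density (PD) correlation analyses.

The pipeline computes one periodogram per consecutive 4-s epoch and averages
it within named frequency bands (PD). PD values are normalised to the mean
of the same band across behavioural states, optionally smoothed into a
24-s moving-average trendline for display, and correlated epoch-by-epoch
between the calcium channel and the EEG bands. Behavioural-episode dynamics
are summarised as the PD change between the last and first third of each
episode (dPD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import BandScheme, Hypnogram, TimeSeries, ValidationError, slice_epochs
from .scoring import EpisodeSet

__all__ = [
    "BandPowerTable",
    "epoch_band_power",
    "normalize_to_state_mean",
    "trendline",
    "CorrelationResult",
    "epoch_correlation",
    "ThirdsResult",
    "episode_thirds",
    "delta_pd_correlation",
]


@dataclass
class BandPowerTable:
    """Per-epoch, per-channel, per-band power.

    ``table`` has a row per epoch and a ``(channel, band)`` MultiIndex on
    the columns. ``normalised`` records whether values have been divided by
    the across-state mean.
    """

    table: pd.DataFrame
    scheme: BandScheme
    epoch_length_s: float = 4.0
    normalised: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.table)

    @property
    def channels(self) -> list[str]:
        return list(self.table.columns.get_level_values(0).unique())

    @property
    def bands(self) -> list[str]:
        return list(self.table.columns.get_level_values(1).unique())

    def power(self, channel: str, band: str) -> pd.Series:
        """Per-epoch power of one channel/band pair."""
        return self.table[(channel, band)]

    def to_tidy(self, h: Hypnogram | None = None) -> pd.DataFrame:
        """Long-format view (epoch, channel, band, power[, state])."""
        out = (
            self.table.stack([0, 1], future_stack=True)
            .rename("power")
            .reset_index()
            .set_axis(["epoch", "channel", "band", "power"], axis=1)
        )
        if h is not None:
            out["state"] = np.asarray(h.labels)[out["epoch"].to_numpy()]
        return out


def epoch_band_power(
    ts: TimeSeries,
    scheme: BandScheme | dict,
    epoch_length_s: float = 4.0,
    channels: Sequence[str] | None = None,
    window: str | None = "hann",
    detrend: str | bool = "constant",
    agg: str = "mean",
) -> BandPowerTable:
    """FFT band power for consecutive fixed-length epochs.

    Each epoch is detrended, Hann-tapered and passed through a periodogram;
    band power is the mean (``agg='mean'``, the default) or sum
    (``agg='sum'``) of periodogram bins whose frequency falls inside the
    band. Set ``window=None, detrend=False`` for a raw periodogram.
    """
    scheme = scheme if isinstance(scheme, BandScheme) else BandScheme(scheme)
    if agg not in ("mean", "sum"):
        raise ValidationError(f"agg must be 'mean' or 'sum', got {agg!r}")
    if channels is None:
        channels = list(ts.labels)
    segs = slice_epochs(ts, epoch_length_s)  # (n_ep, n_ch, m)
    if segs.shape[-1] < 2:
        raise ValidationError("epochs must contain at least 2 samples")
    f, pxx = sps.periodogram(
        segs,
        fs=ts.rate,
        window=window if window is not None else "boxcar",
        detrend=detrend,
        axis=-1,
    )
    nyq = ts.rate / 2
    cols = {}
    for ch in channels:
        ci = ts.labels.index(ch)
        for band, (lo, hi) in scheme.items():
            if lo < 0 or hi > nyq + 1e-9:
                raise ValidationError(
                    f"band {band!r} [{lo}, {hi}] outside [0, {nyq}] Hz"
                )
            mask = scheme.bin_mask(f, band)
            if not mask.any():
                raise ValidationError(
                    f"band {band!r} has no resolvable bin at df={f[1] - f[0]:g} Hz"
                )
            vals = pxx[:, ci, mask]
            cols[(ch, band)] = vals.mean(axis=-1) if agg == "mean" else vals.sum(axis=-1)
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["channel", "band"])
    return BandPowerTable(table=table, scheme=scheme, epoch_length_s=epoch_length_s)


def normalize_to_state_mean(
    bp: BandPowerTable, h: Hypnogram, mode: str = "balanced"
) -> BandPowerTable:
    """Normalise each band's PD to its mean across behavioural states.

    ``mode='balanced'`` (default) divides by the mean of the per-state mean
    PDs over the non-artefact states present, so states contribute equally
    regardless of occupancy; ``mode='pooled'`` divides by the plain mean
    over all non-artefact epochs. Artefact epochs come back as NaN.
    """
    if mode not in ("balanced", "pooled"):
        raise ValidationError(f"unknown normalisation mode {mode!r}")
    if bp.n_epochs != h.n_epochs:
        raise ValidationError(
            f"band power has {bp.n_epochs} epochs, hypnogram {h.n_epochs}"
        )
    good = ~h.mask(["ART"])
    if not good.any():
        raise ValidationError("no artefact-free epochs to normalise against")
    labels = np.asarray(h.labels)
    out = bp.table.copy().astype(float)
    for col in out.columns:
        vals = out[col].to_numpy(float)
        if mode == "balanced":
            means = [
                vals[good & (labels == s)].mean()
                for s in np.unique(labels[good])
            ]
            denom = float(np.mean(means))
        else:
            denom = float(vals[good].mean())
        if denom == 0:
            raise ValidationError(f"zero across-state mean for {col}")
        out[col] = vals / denom
    out[~good] = np.nan
    return BandPowerTable(
        table=out, scheme=bp.scheme, epoch_length_s=bp.epoch_length_s, normalised=True
    )


def trendline(values, window_epochs: int = 6) -> np.ndarray:
    """Centred moving average over ``window_epochs`` epochs (24 s at 4-s
    epochs), advancing one epoch at a time; edges average what is available.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty input")
    s = pd.Series(arr)
    return s.rolling(window_epochs, center=True, min_periods=1).mean().to_numpy()


class CorrelationResult(NamedTuple):
    r: float
    n: int
    p: float


def epoch_correlation(
    x,
    y,
    h: Hypnogram | None = None,
    states: Iterable[str] | None = None,
) -> CorrelationResult:
    """Pearson correlation between two per-epoch PD series.

    Restricted to epochs whose hypnogram label is in ``states`` when given;
    NaN epochs (e.g. artefacts) are dropped pairwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    if states is not None:
        if h is None:
            raise ValidationError("states given without a hypnogram")
        if h.n_epochs != len(x):
            raise ValidationError("hypnogram not aligned with PD series")
        keep &= h.mask(states)
    xs, ys = x[keep], y[keep]
    if len(xs) < 3:
        raise ValidationError(f"need >=3 epochs, have {len(xs)}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValidationError("zero variance in x or y")
    res = stats.pearsonr(xs, ys)
    return CorrelationResult(float(res.statistic), int(len(xs)), float(res.pvalue))


@dataclass
class ThirdsResult:
    """Per-episode PD means in the 1st/2nd/3rd of normalised episode time.

    ``per_episode`` has columns state, start_epoch, end_epoch, pd_1st,
    pd_2nd, pd_3rd and delta_pd (= 3rd - 1st).
    """

    per_episode: pd.DataFrame

    def mean_delta_pd(self, state: str | None = None) -> float:
        df = self.per_episode
        if state is not None:
            df = df[df["state"] == state]
        return float(df["delta_pd"].mean())


def episode_thirds(values, episodes: EpisodeSet) -> ThirdsResult:
    """Split each behavioural episode into thirds of normalised duration.

    Each member epoch is assigned to a third by the position of its midpoint
    in [0, 1] normalised episode time; dPD is the 3rd-third mean minus the
    1st-third mean.
    """
    arr = np.asarray(values, float)
    rows = []
    for ep in episodes:
        span = ep.end_epoch - ep.start_epoch + 1
        if span < 3:
            raise ValidationError("episodes must span at least 3 epochs")
        members = np.asarray(ep.member_epochs, int)
        pos = (members - ep.start_epoch + 0.5) / span
        third = np.minimum((pos * 3).astype(int), 2)
        vals = arr[members]
        means = []
        for t in range(3):
            sel = vals[third == t]
            sel = sel[np.isfinite(sel)]
            if sel.size == 0:
                raise ValidationError(
                    f"episode at epoch {ep.start_epoch}: empty third {t + 1}"
                )
            means.append(float(sel.mean()))
        rows.append(
            {
                "state": ep.state,
                "start_epoch": ep.start_epoch,
                "end_epoch": ep.end_epoch,
                "pd_1st": means[0],
                "pd_2nd": means[1],
                "pd_3rd": means[2],
                "delta_pd": means[2] - means[0],
            }
        )
    return ThirdsResult(per_episode=pd.DataFrame(rows))


def delta_pd_correlation(delta_pd_ca, delta_pd_eeg) -> CorrelationResult:
    """Across-animal Pearson correlation between mean dPD vectors."""
    x = np.asarray(delta_pd_ca, float)
    y = np.asarray(delta_pd_eeg, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError(f"need >=3 animals, have {len(x)}")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), int(len(x)), float(res.pvalue))
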