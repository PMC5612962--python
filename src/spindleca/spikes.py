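"""Juxtacellular firing-rate analyses and the spindle-density regression.

The spike train is turned into an instantaneous rate by convolving a
unit-area impulse train with a 20-ms s.d. Gaussian. Rates are summarised
per pooled behavioural state and inside annotated spindles, compared with
the 2 s immediately before and after each spindle, cross-correlated with
band-filtered field signals during SWS (peak within +-5 s normalised to the
s.d. of the full cross-correlation), and regressed per band against
spindle density (cumulative spindle seconds per 10-s window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import (
    BandScheme,
    Hypnogram,
    SWS_STATES,
    SpikeTrain,
    SpindleAnnotations,
    TimeSeries,
    ValidationError,
    pool_state,
)
from .simulate import bandpass

logger = logging.getLogger(__name__)

__all__ = [
    "RateSeries",
    "instantaneous_rate",
    "state_firing",
    "peri_spindle",
    "rate_band_xcorr",
    "SpindleDensitySeries",
    "spindle_density_regression",
    "detect_spindles_sigma_rms",
]


@dataclass
class RateSeries:
    """Instantaneous firing rate (Hz) on a regular grid."""

    values: np.ndarray
    grid_rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, float).ravel()
        if self.grid_rate <= 0:
            raise ValidationError("grid_rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.grid_rate

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.grid_rate

    def integral(self) -> float:
        """Time integral of the rate; approximately the spike count."""
        return float(self.values.sum() / self.grid_rate)

    def window_mean(self, start_s: float, stop_s: float) -> float:
        a = int(np.floor((start_s - self.t0) * self.grid_rate))
        b = int(np.ceil((stop_s - self.t0) * self.grid_rate))
        a, b = max(a, 0), min(b, len(self.values))
        if b <= a:
            return np.nan
        return float(self.values[a:b].mean())


def instantaneous_rate(
    st: SpikeTrain,
    sigma_s: float = 0.02,
    grid_rate: float = 1000.0,
    duration_s: float | None = None,
) -> RateSeries:
    """Gaussian-smoothed instantaneous firing rate.

    Each spike becomes a unit-area impulse on the output grid (height =
    grid rate, the discrete analogue of an acquisition-frequency-scaled
    Dirac delta); the train is convolved with a unit-area Gaussian kernel
    of standard deviation ``sigma_s`` (20 ms default). The integral of the
    result recovers the spike count.
    """
    if sigma_s <= 0:
        raise ValidationError("sigma_s must be > 0")
    if duration_s is None:
        duration_s = float(st.times_s[-1]) + 5 * sigma_s if len(st) else 1.0
    n = int(np.ceil(duration_s * grid_rate))
    if len(st) and st.times_s[-1] > duration_s:
        raise ValidationError("spike times extend beyond duration_s")
    train = np.zeros(n)
    if len(st):
        idx = np.minimum((st.times_s * grid_rate).astype(int), n - 1)
        np.add.at(train, idx, grid_rate)
    half = int(np.ceil(5 * sigma_s * grid_rate))
    t = np.arange(-half, half + 1) / grid_rate
    kernel = np.exp(-0.5 * (t / sigma_s) ** 2)
    kernel /= kernel.sum()  # exact discrete unit area
    values = sps.fftconvolve(train, kernel, mode="same")
    return RateSeries(values=values, grid_rate=grid_rate)


def state_firing(
    rate: RateSeries,
    h: Hypnogram,
    spindles: SpindleAnnotations | None = None,
) -> pd.Series:
    """Mean firing rate per pooled state (WAKE / SWS / REM) and in spindles.

    The spindle category averages the rate over all annotated intervals.
    Categories without any epoch (or annotation) come back NaN.
    """
    el = h.epoch_length_s
    pooled = np.array([pool_state(s) or "" for s in h.labels])
    out = {}
    for cat in ("WAKE", "SWS", "REM"):
        idx = np.flatnonzero(pooled == cat)
        if len(idx) == 0:
            out[cat] = np.nan
            continue
        means = [rate.window_mean(i * el, (i + 1) * el) for i in idx]
        out[cat] = float(np.nanmean(means))
    if spindles is not None:
        if len(spindles):
            vals = [
                rate.window_mean(on, off)
                for on, off in zip(spindles.onsets, spindles.offsets)
            ]
            out["spindle"] = float(np.nanmean(vals))
        else:
            out["spindle"] = np.nan
    return pd.Series(out)


def peri_spindle(
    rate: RateSeries,
    spindles: SpindleAnnotations,
    pre_s: float = 2.0,
    post_s: float = 2.0,
) -> pd.DataFrame:
    """Firing-rate change around each spindle, as % of the pre-spindle rate.

    Per spindle: 100*(during - pre)/pre and 100*(post - pre)/pre, with
    ``pre``/``post`` the mean rate in the 2 s immediately before/after.
    Spindles whose windows leave the recording, overlap a neighbouring
    spindle, or have a zero pre-spindle rate are skipped (logged).
    """
    rows = []
    onsets, offsets = spindles.onsets, spindles.offsets
    for i, (on, off) in enumerate(zip(onsets, offsets)):
        if on - pre_s < rate.t0 or off + post_s > rate.t0 + rate.duration_s:
            logger.info("spindle %d: window outside recording; skipped", i)
            continue
        if (i > 0 and offsets[i - 1] > on - pre_s) or (
            i + 1 < len(onsets) and onsets[i + 1] < off + post_s
        ):
            logger.info("spindle %d: neighbour inside peri window; skipped", i)
            continue
        pre = rate.window_mean(on - pre_s, on)
        during = rate.window_mean(on, off)
        post = rate.window_mean(off, off + post_s)
        if not pre > 0:
            logger.info("spindle %d: zero pre-spindle rate; skipped", i)
            continue
        rows.append(
            {
                "onset_s": on,
                "pct_during": 100.0 * (during - pre) / pre,
                "pct_post": 100.0 * (post - pre) / pre,
            }
        )
    return pd.DataFrame(rows, columns=["onset_s", "pct_during", "pct_post"])


def _state_sample_mask(h: Hypnogram, states: Iterable[str], rate: float, n: int) -> np.ndarray:
    spe = int(round(h.epoch_length_s * rate))
    per_epoch = h.mask(states)
    mask = np.repeat(per_epoch, spe)
    if len(mask) < n:
        mask = np.concatenate([mask, np.zeros(n - len(mask), bool)])
    return mask[:n]


def rate_band_xcorr(
    rate: RateSeries,
    field: TimeSeries,
    channel: str,
    scheme: BandScheme | dict,
    h: Hypnogram,
    states: Iterable[str] = SWS_STATES,
    max_lag_s: float = 5.0,
) -> pd.Series:
    """Normalised peak cross-correlation between firing rate and each band.

    The field channel is zero-phase band-pass filtered per band and
    cross-correlated with the instantaneous rate over the concatenated
    epochs of the selected states; the statistic is the signed maximum of
    the cross-correlation within +-max_lag_s divided by the s.d. of the
    full cross-correlation function. Requires the rate to live on the
    field's sample grid and >= 60 s of selected state.
    """
    scheme = scheme if isinstance(scheme, BandScheme) else BandScheme(scheme)
    if abs(rate.grid_rate - field.rate) > 1e-9:
        raise ValidationError("rate grid must match the field sampling rate")
    x = field.channel(channel)
    n = min(len(x), len(rate.values))
    mask = _state_sample_mask(h, states, field.rate, n)
    if mask.sum() < 60 * field.rate:
        raise ValidationError("need >= 60 s of the selected states")
    y = rate.values[:n][mask]
    if np.ptp(y) == 0:
        raise ValidationError("rate has zero variance in the selected states")
    y = y - y.mean()
    lag_max = int(round(max_lag_s * field.rate))
    out = {}
    for band, (lo, hi) in scheme.items():
        xf = bandpass(x, field.rate, lo, hi)[:n][mask]
        if np.ptp(xf) == 0:
            raise ValidationError(f"band {band!r} has zero variance")
        xf = xf - xf.mean()
        cc = sps.fftconvolve(y, xf[::-1], mode="full")
        sd = cc.std()
        centre = len(xf) - 1
        window = cc[centre - lag_max : centre + lag_max + 1]
        out[band] = float(window.max() / sd)
    return pd.Series(out)


@dataclass
class SpindleDensitySeries:
    """Per-window spindle density and band power used in the regression."""

    windows: pd.DataFrame  # start_s, density_s, one column per band
    window_s: float


def spindle_density_regression(
    field: TimeSeries,
    channel: str,
    spindles: SpindleAnnotations,
    scheme: BandScheme | dict,
    window_s: float = 10.0,
    overlap_s: float = 0.25,
    welch_seg_s: float = 2.0,
) -> tuple[pd.DataFrame, SpindleDensitySeries]:
    """Per-band linear regression of field power on spindle density.

    The recording is cut into consecutive ``window_s`` windows whose
    successive starts advance by ``window_s - overlap_s``. Per window:
    spindle density = cumulative annotated spindle seconds, and band power
    = Welch power (2-s segments) averaged over the band's bins. An OLS
    line of power on density gives, per band, the slope (the correlation
    measure), its standardised form (slope x sd(density)/sd(power), i.e.
    Pearson r, comparable across bands) and the p-value. Zero density
    variance flags every slope undefined.
    """
    scheme = scheme if isinstance(scheme, BandScheme) else BandScheme(scheme)
    if not 0 <= overlap_s < window_s:
        raise ValidationError("need 0 <= overlap_s < window_s")
    step = window_s - overlap_s
    x = field.channel(channel)
    total = field.duration_s
    starts = []
    t = 0.0
    while t + window_s <= total + 1e-9:
        starts.append(t)
        t += step
    if len(starts) < 3:
        raise ValidationError("recording too short for the window scheme")
    nper = int(round(welch_seg_s * field.rate))
    dens = np.array([spindles.density(s, s + window_s) for s in starts])
    powers: dict[str, np.ndarray] = {b: np.empty(len(starts)) for b in scheme}
    for i, s in enumerate(starts):
        a = int(round(s * field.rate))
        b = a + int(round(window_s * field.rate))
        f, pxx = sps.welch(x[a:b], fs=field.rate, nperseg=min(nper, b - a))
        for band in scheme:
            m = scheme.bin_mask(f, band)
            if not m.any():
                raise ValidationError(f"band {band!r} unresolvable in Welch grid")
            powers[band][i] = pxx[m].mean()
    wdf = pd.DataFrame({"start_s": starts, "density_s": dens, **powers})
    rows = []
    flat = np.ptp(dens) == 0
    for band in scheme:
        if flat:
            rows.append(
                {"band": band, "slope": np.nan, "r": np.nan, "p": np.nan,
                 "undefined": True}
            )
            continue
        res = stats.linregress(dens, powers[band])
        rows.append(
            {
                "band": band,
                "slope": float(res.slope),
                "r": float(res.rvalue),
                "p": float(res.pvalue),
                "undefined": False,
            }
        )
    return (
        pd.DataFrame(rows).set_index("band"),
        SpindleDensitySeries(windows=wdf, window_s=window_s),
    )


def detect_spindles_sigma_rms(
    ts: TimeSeries,
    channel: str,
    threshold_sd: float = 2.5,
    min_dur_s: float = 0.5,
    max_dur_s: float = 3.0,
    smooth_s: float = 0.1,
) -> SpindleAnnotations:
    """Convenience sigma-RMS threshold spindle detector (non-canonical).

    Spindle annotation is a manual, visual procedure on the LFP; this
    helper only provides a rough automatic stand-in: the 9-16 Hz filtered
    signal's smoothed RMS envelope is thresholded at mean + k s.d. and
    supra-threshold runs of plausible duration become intervals.
    """
    x = bandpass(ts.channel(channel), ts.rate, 9.0, 16.0)
    w = max(1, int(round(smooth_s * ts.rate)))
    env = np.sqrt(np.convolve(x**2, np.ones(w) / w, mode="same"))
    thr = env.mean() + threshold_sd * env.std()
    above = env > thr
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(above)]))
    iv = []
    for a, b in zip(starts, ends):
        dur = (b - a) / ts.rate
        if min_dur_s <= dur <= max_dur_s:
            iv.append((a / ts.rate, b / ts.rate))
    return SpindleAnnotations(np.asarray(iv).reshape(-1, 2))
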