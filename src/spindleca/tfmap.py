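"""Time-frequency cross-correlation between calcium and EEG band energy.

A 4-s search window advances along the recording in steps of 250 ms (the
500-ms TFROI length minus its 50% overlap). At each position the mean
spectral "energy" of every EEG band is computed over a 500-ms Hann-tapered
TFROI, while the calcium channel's slow-band (0.1-1 Hz) energy -- not
resolvable on 500 ms -- is computed over the full 4-s window centred at the
same position. Spearman rank correlation between the calcium energy series
and each lagged EEG energy series yields a band x lag heatmap with
per-cell two-sided p-values; the lag axis is the EEG TFROI centre minus
the calcium window centre, so a peak at negative lag means the EEG event
precedes the calcium event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import BandScheme, Hypnogram, TimeSeries, ValidationError

__all__ = [
    "TFConfig",
    "TFHeatmap",
    "tfroi_energy",
    "ca_slow_energy",
    "restrict_to_state",
    "crosscorr_map",
    "tf_heatmap",
]


@dataclass
class TFConfig:
    search_window_s: float = 4.0
    tfroi_s: float = 0.5
    tfroi_overlap: float = 0.5
    max_lag_s: float = 2.0
    ca_band: tuple = (0.1, 1.0)

    def __post_init__(self):
        if not self.tfroi_s < self.search_window_s:
            raise ValidationError("tfroi_s must be < search_window_s")
        if not 0 <= self.tfroi_overlap < 1:
            raise ValidationError("tfroi_overlap must be in [0, 1)")
        if self.max_lag_s <= 0:
            raise ValidationError("max_lag_s must be > 0")

    @property
    def step_s(self) -> float:
        return self.tfroi_s * (1.0 - self.tfroi_overlap)


def _segment_energy(
    x: np.ndarray,
    rate: float,
    seg_samples: int,
    step_samples: int,
    band: tuple,
    band_name: str = "band",
    chunk: int = 8192,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Hann-tapered |FFT|^2 over band bins for strided segments.

    Returns (energies, centre_times).
    """
    n = len(x)
    if n < seg_samples:
        raise ValidationError("signal shorter than one segment")
    starts = np.arange(0, n - seg_samples + 1, step_samples)
    f = np.fft.rfftfreq(seg_samples, d=1.0 / rate)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ValidationError(
            f"{band_name} [{lo}, {hi}] Hz unresolvable on a "
            f"{seg_samples / rate:g} s segment (df={f[1]:g} Hz)"
        )
    win = np.hanning(seg_samples)
    energies = np.empty(len(starts))
    for c0 in range(0, len(starts), chunk):
        idx = starts[c0 : c0 + chunk, None] + np.arange(seg_samples)[None, :]
        segs = x[idx] * win
        ft = np.fft.rfft(segs, axis=-1)
        energies[c0 : c0 + chunk] = (np.abs(ft[:, mask]) ** 2).mean(axis=-1)
    centres = (starts + seg_samples / 2.0) / rate
    return energies, centres


def tfroi_energy(
    ts: TimeSeries, channel: str, band: tuple, cfg: TFConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position 500-ms TFROI energy of one EEG band.

    Positions advance by the TFROI step over the whole recording. Returns
    (energies, centre_times_s). Bands narrower than the 500-ms frequency
    resolution raise.
    """
    cfg = cfg or TFConfig()
    x = ts.channel(channel)
    seg = int(round(cfg.tfroi_s * ts.rate))
    step = int(round(cfg.step_s * ts.rate))
    return _segment_energy(x, ts.rate, seg, step, band, band_name=f"band {band}")


def ca_slow_energy(
    ts: TimeSeries, channel: str = "CA", cfg: TFConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Calcium slow-band energy over the full search window per position.

    The 0.1-1 Hz band cannot be estimated from a 500-ms TFROI, so the
    calcium channel uses the whole 4-s search window centred on each grid
    position.
    """
    cfg = cfg or TFConfig()
    x = ts.channel(channel)
    seg = int(round(cfg.search_window_s * ts.rate))
    step = int(round(cfg.step_s * ts.rate))
    return _segment_energy(
        x, ts.rate, seg, step, cfg.ca_band, band_name="calcium band"
    )


def restrict_to_state(
    times: np.ndarray, h: Hypnogram, states: Iterable[str]
) -> np.ndarray:
    """Boolean mask keeping positions whose centre epoch is in ``states``."""
    times = np.asarray(times, float)
    idx = (times / h.epoch_length_s).astype(int)
    idx = np.minimum(idx, h.n_epochs - 1)
    keep = np.isin(np.asarray(h.labels)[idx], list(states))
    keep &= times <= h.duration_s
    return keep


@dataclass
class TFHeatmap:
    """Band x lag Spearman rho and p-value maps.

    ``rho`` and ``p`` are DataFrames with bands as rows and lag (s) as
    columns; undefined cells (constant energy series) are NaN.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int

    @property
    def lags_s(self) -> np.ndarray:
        return self.rho.columns.to_numpy(float)

    def peak(self) -> tuple[str, float, float]:
        """(band, lag_s, rho) of the largest |rho| over defined cells."""
        arr = self.rho.to_numpy(float)
        if not np.isfinite(arr).any():
            raise ValidationError("heatmap has no defined cells")
        flat = np.nanargmax(np.abs(arr))
        i, j = np.unravel_index(flat, arr.shape)
        return (
            str(self.rho.index[i]),
            float(self.rho.columns[j]),
            float(arr[i, j]),
        )


def crosscorr_map(
    ca_energy: np.ndarray,
    eeg_energies: dict[str, np.ndarray],
    cfg: TFConfig | None = None,
    valid_mask: np.ndarray | None = None,
    min_positions: int = 30,
) -> TFHeatmap:
    """Spearman correlation between calcium and lagged EEG band energies.

    All series must share the TFROI position grid. For each band and each
    lag on the grid within +-max_lag_s, the calcium series at positions t
    is rank-correlated with the band energy at positions t + lag.
    ``valid_mask`` (e.g. from :func:`restrict_to_state`) selects the
    calcium positions entering the correlation.
    """
    cfg = cfg or TFConfig()
    ca = np.asarray(ca_energy, float)
    npos = len(ca)
    for b, e in eeg_energies.items():
        if len(e) != npos:
            raise ValidationError(f"band {b!r} energy grid mismatch")
    if valid_mask is None:
        valid_mask = np.ones(npos, bool)
    lag_steps = int(round(cfg.max_lag_s / cfg.step_s))
    lags = np.arange(-lag_steps, lag_steps + 1)
    lag_seconds = np.round(lags * cfg.step_s, 9)
    bands = list(eeg_energies)
    rho = np.full((len(bands), len(lags)), np.nan)
    pval = np.full_like(rho, np.nan)
    n_used = 0
    t = np.flatnonzero(valid_mask)
    for j, lag in enumerate(lags):
        tt = t[(t + lag >= 0) & (t + lag < npos)]
        if len(tt) < min_positions:
            raise ValidationError(
                f"only {len(tt)} valid positions at lag {lag_seconds[j]} s "
                f"(need >= {min_positions})"
            )
        n_used = max(n_used, len(tt))
        ca_t = ca[tt]
        if np.ptp(ca_t) == 0:
            continue  # undefined cells stay NaN
        for i, b in enumerate(bands):
            e_t = eeg_energies[b][tt + lag]
            if np.ptp(e_t) == 0:
                continue
            res = stats.spearmanr(ca_t, e_t)
            rho[i, j] = res.statistic
            pval[i, j] = res.pvalue
    rho_df = pd.DataFrame(rho, index=bands, columns=lag_seconds)
    p_df = pd.DataFrame(pval, index=bands, columns=lag_seconds)
    return TFHeatmap(rho=rho_df, p=p_df, n=n_used)


def tf_heatmap(
    eeg: TimeSeries,
    ca: TimeSeries,
    scheme: BandScheme | dict,
    eeg_channel: str = "EEG-FP",
    ca_channel: str = "CA",
    h: Hypnogram | None = None,
    states: Iterable[str] | None = None,
    cfg: TFConfig | None = None,
) -> TFHeatmap:
    """End-to-end heatmap for one EEG channel against the calcium channel.

    Computes TFROI energies for every band in ``scheme``, the calcium
    slow-band energy on the matching grid, optionally restricts positions
    to the given vigilance states, and correlates.
    """
    cfg = cfg or TFConfig()
    scheme = scheme if isinstance(scheme, BandScheme) else BandScheme(scheme)
    ca_e, ca_t = ca_slow_energy(ca, channel=ca_channel, cfg=cfg)
    energies = {}
    for band in scheme:
        e, t = tfroi_energy(eeg, eeg_channel, scheme[band], cfg=cfg)
        # align the (shorter) calcium grid: calcium windows are longer, so
        # their centres start later; match centres on the common grid
        offset = int(round((ca_t[0] - t[0]) / cfg.step_s))
        energies[band] = e[offset : offset + len(ca_e)]
        if len(energies[band]) < len(ca_e):
            ca_e = ca_e[: len(energies[band])]
            ca_t = ca_t[: len(energies[band])]
    energies = {b: e[: len(ca_e)] for b, e in energies.items()}
    mask = None
    if states is not None:
        if h is None:
            raise ValidationError("states given without a hypnogram")
        mask = restrict_to_state(ca_t, h, states)
    return crosscorr_map(ca_e, energies, cfg=cfg, valid_mask=mask)
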