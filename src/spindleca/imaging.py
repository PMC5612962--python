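"""Two-photon ROI processing: dF/F0, state activity, population synchrony.

Raw per-ROI fluorescence is normalised with a sliding-baseline dF/F0 where
F0 is the mean of the lowest third of raw values inside a 20-s window around
each sample. Activity is summarised per vigilance state as percentage change
from active wake. Population synchrony per 4-s epoch is the Fisher-z mean
of all pairwise Pearson correlations mapped back through tanh to a [0, 1]
level, and ROIs are partitioned by the sign of their correlation with
sigma-band EEG power during slow-wave sleep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import Hypnogram, ROIMatrix, SWS_STATES, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .transients import TransientConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DffConfig",
    "dff",
    "epoch_means",
    "state_activity",
    "SynchronySeries",
    "synchrony",
    "PartitionResult",
    "partition_by_sigma_correlation",
]

_R_CLIP = 1.0 - 1e-6


@dataclass
class DffConfig:
    window_s: float = 20.0
    slide_s: float = 0.005
    baseline_fraction: float = 1.0 / 3.0
    centred: bool = True

    def __post_init__(self):
        if self.window_s <= 0 or self.slide_s <= 0:
            raise ValidationError("window_s and slide_s must be > 0")
        if not 0 < self.baseline_fraction < 1:
            raise ValidationError("baseline_fraction must be in (0, 1)")


def _sliding_lower_mean(
    x: np.ndarray, w: int, frac: float, centred: bool, block: int = 4096
) -> np.ndarray:
    """Per-sample mean of the lowest ``frac`` of values in a w-sample
    window (centred or trailing), truncated at the edges."""
    n = len(x)
    half_l = w // 2 if centred else w - 1
    half_r = w - 1 - half_l if centred else 0
    out = np.empty(n)
    for b0 in range(0, n, block):
        b1 = min(b0 + block, n)
        for i in range(b0, b1):
            lo = max(0, i - half_l)
            hi = min(n, i + half_r + 1)
            win = x[lo:hi]
            k = max(1, int(np.ceil(len(win) * frac)))
            out[i] = np.partition(win, k - 1)[:k].mean()
    return out


def dff(roi: ROIMatrix, cfg: DffConfig | None = None) -> ROIMatrix:
    """Sliding-baseline dF/F0 per ROI.

    F0 at each sample is the mean of the lowest third of raw fluorescence
    in the surrounding 20-s window (truncated at the recording edges; the
    5-ms slide re-evaluates the window at least every sample at typical
    frame rates). Output is (F - F0) / F0.
    """
    cfg = cfg or DffConfig()
    stride = max(1, int(round(cfg.slide_s * roi.rate)))
    w = max(2, int(round(cfg.window_s * roi.rate)))
    out = np.empty_like(roi.data, dtype=float)
    for r in range(roi.n_rois):
        x = roi.data[r].astype(float)
        if stride == 1:
            f0 = _sliding_lower_mean(x, w, cfg.baseline_fraction, cfg.centred)
        else:
            anchors = np.arange(0, roi.n_samples, stride)
            f0a = _sliding_lower_mean(
                x[anchors], max(2, w // stride), cfg.baseline_fraction, cfg.centred
            )
            f0 = np.interp(np.arange(roi.n_samples), anchors, f0a)
        if (f0 <= 0).any():
            raise ValidationError(f"ROI {roi.roi_ids[r]}: non-positive baseline F0")
        out[r] = (x - f0) / f0
    return ROIMatrix(data=out, rate=roi.rate, roi_ids=list(roi.roi_ids), is_dff=True)


def epoch_means(roi: ROIMatrix, epoch_length_s: float = 4.0) -> np.ndarray:
    """(n_rois, n_epochs) mean trace value per consecutive epoch."""
    m = int(round(epoch_length_s * roi.rate))
    n_ep = roi.n_samples // m
    if n_ep == 0:
        raise ValidationError("recording shorter than one epoch")
    return roi.data[:, : n_ep * m].reshape(roi.n_rois, n_ep, m).mean(axis=-1)


def state_activity(
    dff_roi: ROIMatrix,
    h: Hypnogram,
    transient_cfg: "TransientConfig | None" = None,
) -> dict[str, pd.DataFrame]:
    """Per-ROI, per-state activity as percentage change from active wake.

    Reports the state-mean dF/F0 (and, when ``transient_cfg`` is given,
    the transient frequency in events/min from the multi-pass detector) as
    ``100 * (state - AW) / AW`` per ROI. Requires at least one AW epoch.
    """
    labels = np.asarray(h.labels)
    if not (labels == "AW").any():
        raise ValidationError("active wake absent; cannot express change from AW")
    em = epoch_means(dff_roi, h.epoch_length_s)
    n_ep = min(em.shape[1], h.n_epochs)
    em = em[:, :n_ep]
    labels = labels[:n_ep]
    states = [s for s in ("AW", "QW", "NREM", "IS", "REM") if (labels == s).any()]
    mean_dff = pd.DataFrame(
        {s: em[:, labels == s].mean(axis=1) for s in states},
        index=list(dff_roi.roi_ids),
    )
    out = {"mean_dff": mean_dff, "mean_dff_pct_change": _pct_change_from_aw(mean_dff)}
    if transient_cfg is not None:
        from .transients import detect_transients, normalize_signal, transient_statistics

        rates = {}
        for r, rid in enumerate(dff_roi.roi_ids):
            tset = detect_transients(
                normalize_signal(dff_roi.data[r]), dff_roi.rate, transient_cfg
            )
            summary, _ = transient_statistics(tset, h)
            rates[rid] = summary["rate_per_min"]
        freq = pd.DataFrame(rates).T[states]
        out["transient_rate_per_min"] = freq
        out["transient_rate_pct_change"] = _pct_change_from_aw(freq)
    return out


def _pct_change_from_aw(df: pd.DataFrame) -> pd.DataFrame:
    base = df["AW"]
    return 100.0 * df.sub(base, axis=0).div(base.replace(0, np.nan), axis=0)


@dataclass
class SynchronySeries:
    """Per-epoch population synchrony in [0, 1].

    ``values`` floors negative Fisher-mean correlations at 0 (the reported
    series); ``raw`` keeps the signed tanh of the mean z. Epochs where
    fewer than two ROIs have variance are NaN.
    """

    values: np.ndarray
    raw: np.ndarray
    n_rois: int
    epoch_length_s: float
    states: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    def state_mean(self, states: Iterable[str]) -> float:
        if self.states is None:
            raise ValidationError("no hypnogram attached")
        sel = np.isin(self.states, list(states)) & np.isfinite(self.values)
        return float(self.values[sel].mean())


def synchrony(
    dff_roi: ROIMatrix,
    h: Hypnogram | None = None,
    epoch_length_s: float = 4.0,
) -> SynchronySeries:
    """Fisher-averaged pairwise correlation per 4-s epoch.

    All pairwise Pearson coefficients within the epoch are clipped to
    +-(1 - 1e-6), Fisher z-transformed, averaged, and mapped back with
    tanh; the reported series floors negative values at 0. ROIs with zero
    variance in an epoch drop out of that epoch's pairs.
    """
    if dff_roi.n_rois < 2:
        raise ValidationError("need at least 2 ROIs")
    el = h.epoch_length_s if h is not None else epoch_length_s
    m = int(round(el * dff_roi.rate))
    if m < 2:
        raise ValidationError("epoch must contain at least 2 samples")
    n_ep = dff_roi.n_samples // m
    raw = np.full(n_ep, np.nan)
    for e in range(n_ep):
        seg = dff_roi.data[:, e * m : (e + 1) * m]
        keep = seg.std(axis=1) > 0
        if keep.sum() < 2:
            continue
        r = np.corrcoef(seg[keep])
        iu = np.triu_indices_from(r, k=1)
        z = np.arctanh(np.clip(r[iu], -_R_CLIP, _R_CLIP))
        raw[e] = np.tanh(z.mean())
    values = np.where(np.isnan(raw), np.nan, np.clip(raw, 0.0, None))
    states = None
    if h is not None:
        states = np.asarray(h.labels)[:n_ep]
    return SynchronySeries(
        values=values,
        raw=raw,
        n_rois=dff_roi.n_rois,
        epoch_length_s=el,
        states=states,
    )


@dataclass
class PartitionResult:
    """Sign partition of ROIs by their correlation with sigma power.

    ``assignments`` maps ROI id -> 'positive' / 'negative' (ties to
    positive); ``sigma_r`` holds the per-ROI coefficients; ``profiles``
    has one row per group and one column per EEG band with the group-mean
    correlation between ROI activity and that band's power.
    """

    assignments: pd.Series
    sigma_r: pd.Series
    profiles: pd.DataFrame

    @property
    def fraction_positive(self) -> float:
        return float((self.assignments == "positive").mean())


def partition_by_sigma_correlation(
    dff_roi: ROIMatrix,
    sigma_pd,
    h: Hypnogram,
    band_pd: pd.DataFrame | None = None,
    states: Iterable[str] = SWS_STATES,
) -> PartitionResult:
    """Split ROIs by the sign of their sigma-power correlation during SWS.

    Per ROI, the epoch-mean dF/F0 is Pearson-correlated with the sigma PD
    over the selected epochs; the ROI joins the positive group when
    r >= 0. ``band_pd`` (per-epoch power, one column per band) yields the
    per-group per-band correlation profiles. Zero-variance ROIs are
    excluded with a log entry.
    """
    sigma_pd = np.asarray(sigma_pd, float)
    if len(sigma_pd) != h.n_epochs:
        raise ValidationError("sigma PD not aligned with hypnogram")
    em = epoch_means(dff_roi, h.epoch_length_s)
    n_ep = min(em.shape[1], h.n_epochs)
    sel = h.mask(states)[:n_ep] & np.isfinite(sigma_pd[:n_ep])
    if sel.sum() < 3:
        raise ValidationError(f"need >=3 epochs in {sorted(states)}")
    assignments = {}
    sigma_r = {}
    kept_rows = {}
    for r, rid in enumerate(dff_roi.roi_ids):
        x = em[r, :n_ep][sel]
        if np.ptp(x) == 0:
            logger.warning("ROI %s has zero variance; excluded from partition", rid)
            continue
        rr = float(stats.pearsonr(x, sigma_pd[:n_ep][sel]).statistic)
        sigma_r[rid] = rr
        assignments[rid] = "positive" if rr >= 0 else "negative"
        kept_rows[rid] = x
    if not assignments:
        raise ValidationError("no ROI with variance in the selected epochs")
    profiles = pd.DataFrame()
    if band_pd is not None:
        band_pd = band_pd.iloc[:n_ep]
        prof: dict[str, dict[str, float]] = {"positive": {}, "negative": {}}
        for band in band_pd.columns:
            bvals = band_pd[band].to_numpy(float)[sel]
            for group in ("positive", "negative"):
                rs = [
                    float(stats.pearsonr(kept_rows[rid], bvals).statistic)
                    for rid, g in assignments.items()
                    if g == group
                ]
                prof[group][band] = float(np.mean(rs)) if rs else np.nan
        profiles = pd.DataFrame(prof).T
    return PartitionResult(
        assignments=pd.Series(assignments, name="group"),
        sigma_r=pd.Series(sigma_r, name="sigma_r"),
        profiles=profiles,
    )
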