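"""Synthetic polysomnographic recordings with known ground truth.

The generator emulates the statistical structure the analyses assume in a
rodent light-phase recording: a semi-Markov 5-state hypnogram on 4-s epochs
(IS only enters from NREM and lasts at least 6 epochs), two EEG derivations
plus EMG at 200 Hz whose band content is state-dependent (slow-wave activity
in NREM, parietal theta in AW/REM/IS, sigma spindle bursts of 0.5-3 s in
NREM/IS), a fibre-optic calcium channel built from a slow 0.1-1 Hz
oscillation plus half-sine transients that can be coupled to spindle
occurrence, two-photon ROI trace matrices with a known common-factor
correlation structure, and delta-phase-modulated Poisson spike trains.

Every planted event is returned as ground truth so detector recall, epoch
correlations and regression slopes can be checked against known answers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    Hypnogram,
    ROIMatrix,
    SpikeTrain,
    SpindleAnnotations,
    TimeSeries,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimRecording",
    "generate_hypnogram",
    "generate_eeg",
    "generate_ca_population",
    "generate_roi_traces",
    "generate_spikes",
    "simulate_recording",
]

logger = logging.getLogger(__name__)

_SIM_STATES = ("AW", "QW", "NREM", "IS", "REM")


def bandpass(x: np.ndarray, rate: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    A band whose upper edge reaches the Nyquist frequency degenerates to a
    high-pass at the lower edge.
    """
    nyq = rate / 2.0
    if hi >= nyq:
        sos = sps.butter(order, lo, btype="highpass", fs=rate, output="sos")
    else:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


@dataclass
class SimConfig:
    """Study conditions for one simulated recording.

    Defaults describe a 2-h light-phase recording digitised at 200 Hz.
    Bout-length means are in epochs; EEG component amplitudes are the RMS
    of each band-limited noise component per state (arbitrary microvolt-like
    units); spindle bursts carry a weak second harmonic so that, as for real
    non-sinusoidal spindle waveforms, some event energy falls in the beta
    band. ``coupling_strength`` is the probability that a spindle triggers
    a calcium transient at a lag drawn uniformly from ``coupling_lag_s``.
    """

    seed: int = 0
    duration_s: float = 7200.0
    rate: float = 200.0
    epoch_length_s: float = 4.0

    # hypnogram: geometric bout lengths + bout-level transition chain
    mean_bout_epochs: dict = field(
        default_factory=lambda: {"AW": 14, "QW": 9, "NREM": 16, "IS": 11, "REM": 18}
    )
    transitions: dict = field(
        default_factory=lambda: {
            "AW": {"QW": 0.65, "NREM": 0.35},
            "QW": {"AW": 0.4, "NREM": 0.6},
            "NREM": {"IS": 0.4, "QW": 0.4, "AW": 0.2},
            "IS": {"NREM": 0.45, "REM": 0.313, "QW": 0.197, "AW": 0.04},
            "REM": {"AW": 0.4, "QW": 0.6},
        }
    )
    is_min_epochs: int = 6

    # EEG band-limited component RMS amplitudes per state
    swa_amp: dict = field(
        default_factory=lambda: {"AW": 6, "QW": 8, "NREM": 40, "IS": 15, "REM": 5}
    )
    theta_amp: dict = field(
        default_factory=lambda: {"AW": 25, "QW": 6, "NREM": 5, "IS": 20, "REM": 25}
    )
    sigma_bg_amp: dict = field(
        default_factory=lambda: {"AW": 4, "QW": 4, "NREM": 8, "IS": 18, "REM": 4}
    )
    broadband_amp: float = 5.0
    ff_theta_factor: float = 0.2
    emg_amp: dict = field(
        default_factory=lambda: {"AW": 20, "QW": 12, "NREM": 3, "IS": 3, "REM": 1}
    )

    # spindles
    spindle_rate_per_min: dict = field(
        default_factory=lambda: {"NREM": 6.0, "IS": 12.0}
    )
    spindle_duration_s: tuple = (0.5, 3.0)
    spindle_freq_hz: float = 12.0
    spindle_amp: float = 50.0
    spindle_harmonic: float = 0.3
    spindle_ff_factor: float = 0.8

    # calcium population channel
    ca_slow_amp: float = 0.05
    ca_noise_amp: float = 0.05
    ca_transient_rate_per_min: float = 3.0
    ca_state_rate_multiplier: dict = field(
        default_factory=lambda: {s: 1.0 for s in _SIM_STATES}
    )
    ca_transient_duration_s: tuple = (0.5, 4.0)
    ca_transient_amp: tuple = (1.0, 2.5)
    coupling_strength: float = 1.0
    coupling_lag_s: tuple = (0.0, 1.0)

    # two-photon ROI traces
    n_rois: int = 20
    roi_rate: float = 30.0
    roi_loading: dict = field(
        default_factory=lambda: {"AW": 0.5, "QW": 0.5, "NREM": 1.0, "IS": 1.3, "REM": 0.7}
    )
    roi_noise_sd: float = 1.0
    roi_baseline: float = 100.0
    roi_gain: float = 10.0
    roi_identical: bool = False
    roi_frac_positive: float = 0.75
    roi_sigma_coupling: float = 0.0

    # juxtacellular spikes
    spike_state_rate: dict = field(
        default_factory=lambda: {s: 5.0 for s in _SIM_STATES}
    )
    spike_delta_depth: float = 0.8
    spike_acquisition_rate: float = 25000.0

    def __post_init__(self):
        if self.duration_s < self.epoch_length_s:
            raise ValidationError("duration shorter than one epoch")
        if not 0 <= self.coupling_strength <= 1:
            raise ValidationError("coupling_strength must be in [0, 1]")
        if not 0 <= self.roi_frac_positive <= 1:
            raise ValidationError("roi_frac_positive must be in [0, 1]")
        for name in ("spindle_duration_s", "ca_transient_duration_s"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must be a positive range")
        if self.ca_transient_rate_per_min < 0 or any(
            v < 0 for v in self.spindle_rate_per_min.values()
        ):
            raise ValidationError("event rates must be >= 0")
        for s, row in self.transitions.items():
            tot = sum(row.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValidationError(f"transitions out of {s} sum to {tot}, not 1")
            if any(p < 0 or p > 1 for p in row.values()):
                raise ValidationError("transition probabilities must be in [0, 1]")
            if row.get("IS", 0) > 0 and s != "NREM":
                raise ValidationError("IS may only be entered from NREM")

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // self.epoch_length_s)

    def stationary_occupancy(self) -> dict:
        """Expected long-run fraction of time in each state.

        Occupancy is proportional to the stationary visit frequency of the
        bout-level transition chain times the mean bout length.
        """
        states = list(self.transitions)
        M = np.array(
            [[self.transitions[a].get(b, 0.0) for b in states] for a in states]
        )
        w, v = np.linalg.eig(M.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        occ = pi * np.array([self.mean_bout_epochs.get(s, 1.0) for s in states])
        occ /= occ.sum()
        return dict(zip(states, occ))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks downstream."""

    hypnogram: Hypnogram
    spindles: SpindleAnnotations
    ca_transients: pd.DataFrame  # onset_s, offset_s, amplitude, coupled
    roi_expected_corr: dict | None = None
    roi_signs: np.ndarray | None = None
    spike_state_rates: dict | None = None


@dataclass
class SimRecording:
    """One complete simulated session."""

    config: SimConfig
    hypnogram: Hypnogram
    eeg: TimeSeries
    spindles: SpindleAnnotations
    ca: TimeSeries
    truth: GroundTruth
    rois: ROIMatrix | None = None
    spikes: SpikeTrain | None = None


def _bout_length(state: str, cfg: SimConfig, rng: np.random.Generator) -> int:
    mean = float(cfg.mean_bout_epochs.get(state, 1.0))
    if state == "IS":
        extra_mean = max(mean - cfg.is_min_epochs + 1, 1.0)
        return cfg.is_min_epochs - 1 + int(rng.geometric(1.0 / extra_mean))
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def generate_hypnogram(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> Hypnogram:
    """Semi-Markov 5-state hypnogram in 4-s epochs.

    Bout lengths are geometric around the configured means; IS bouts are at
    least ``is_min_epochs`` long and, by construction of the transition
    chain, always immediately follow NREM. Reproducible under a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_epochs
    if n < 1:
        raise ValidationError("duration shorter than one epoch")
    states = list(cfg.transitions)
    start_choices = [s for s in states if s != "IS"]
    occ = cfg.stationary_occupancy()
    p0 = np.array([occ[s] for s in start_choices])
    state = rng.choice(start_choices, p=p0 / p0.sum())
    labels: list[str] = []
    while len(labels) < n:
        labels.extend([state] * _bout_length(state, cfg, rng))
        nxt = cfg.transitions[state]
        state = rng.choice(list(nxt), p=np.array(list(nxt.values())))
    labels = labels[:n]
    # trimming may leave a truncated IS run at the end; IS shorter than the
    # minimum is indistinguishable from NREM, so fold it back
    k = n
    while k > 0 and labels[k - 1] == "IS":
        k -= 1
    if 0 < n - k < cfg.is_min_epochs:
        labels[k:] = ["NREM"] * (n - k)
    return Hypnogram(np.asarray(labels), epoch_length_s=cfg.epoch_length_s)


def _state_envelope(hyp: Hypnogram, amp: Mapping[str, float], samples_per_epoch: int) -> np.ndarray:
    per_epoch = np.array([float(amp.get(s, 0.0)) for s in hyp.labels])
    return np.repeat(per_epoch, samples_per_epoch)


def _band_noise(n: int, rate: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    x = bandpass(rng.standard_normal(n), rate, lo, hi)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spindle_waveform(
    dur_s: float, rate: float, freq: float, amp: float, harmonic: float, phase: float
) -> np.ndarray:
    m = max(int(round(dur_s * rate)), 2)
    t = np.arange(m) / rate
    env = np.hanning(m)
    w = np.sin(2 * np.pi * freq * t + phase)
    if harmonic:
        w = w + harmonic * np.sin(4 * np.pi * freq * t + 2 * phase)
    return amp * env * w


def _place_events(
    hyp: Hypnogram,
    rate_per_min: Mapping[str, float],
    dur_range: tuple,
    total_s: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Poisson event onsets within epochs of the given states; durations
    uniform in ``dur_range``; overlapping or out-of-range events dropped."""
    ev: list[tuple[float, float]] = []
    el = hyp.epoch_length_s
    for i, s in enumerate(hyp.labels):
        lam = rate_per_min.get(str(s), 0.0) * el / 60.0
        if lam <= 0:
            continue
        for _ in range(rng.poisson(lam)):
            onset = i * el + rng.uniform(0, el)
            dur = rng.uniform(*dur_range)
            if onset + dur <= total_s:
                ev.append((onset, onset + dur))
    ev.sort()
    kept: list[tuple[float, float]] = []
    for on, off in ev:
        if not kept or on >= kept[-1][1]:
            kept.append((on, off))
    return kept


def generate_eeg(
    hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[TimeSeries, SpindleAnnotations]:
    """EEG-FF, EEG-FP and EMG channels plus planted spindle annotations.

    Each channel is a sum of band-limited noise components whose RMS is set
    per state; spindles are Hann-enveloped sigma-frequency bursts inserted
    in NREM/IS epochs at the configured rates and returned exactly as
    planted.
    """
    if hyp.n_epochs == 0:
        raise ValidationError("empty hypnogram")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spe = int(round(hyp.epoch_length_s * cfg.rate))
    n = hyp.n_epochs * spe
    total_s = n / cfg.rate

    swa = _band_noise(n, cfg.rate, 0.5, 4.0, rng)
    theta = _band_noise(n, cfg.rate, 5.0, 9.0, rng)
    sigma = _band_noise(n, cfg.rate, 9.0, 16.0, rng)

    swa_env = _state_envelope(hyp, cfg.swa_amp, spe)
    theta_env = _state_envelope(hyp, cfg.theta_amp, spe)
    sigma_env = _state_envelope(hyp, cfg.sigma_bg_amp, spe)

    ff = (
        swa * swa_env
        + theta * theta_env * cfg.ff_theta_factor
        + sigma * sigma_env
        + cfg.broadband_amp * rng.standard_normal(n)
    )
    fp = (
        swa * swa_env
        + theta * theta_env
        + sigma * sigma_env
        + cfg.broadband_amp * rng.standard_normal(n)
    )
    emg = _state_envelope(hyp, cfg.emg_amp, spe) * rng.standard_normal(n)

    events = _place_events(
        hyp, cfg.spindle_rate_per_min, cfg.spindle_duration_s, total_s, rng
    )
    for on, off in events:
        w = _spindle_waveform(
            off - on,
            cfg.rate,
            cfg.spindle_freq_hz,
            cfg.spindle_amp,
            cfg.spindle_harmonic,
            rng.uniform(0, 2 * np.pi),
        )
        a = int(round(on * cfg.rate))
        b = min(a + len(w), n)
        fp[a:b] += w[: b - a]
        ff[a:b] += cfg.spindle_ff_factor * w[: b - a]

    ts = TimeSeries(
        data=np.vstack([ff, fp, emg]),
        rate=cfg.rate,
        labels=["EEG-FF", "EEG-FP", "EMG"],
        units=["uV", "uV", "uV"],
    )
    return ts, SpindleAnnotations(np.asarray(events).reshape(-1, 2))


def generate_ca_population(
    hyp: Hypnogram,
    spindles: SpindleAnnotations,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TimeSeries, pd.DataFrame]:
    """Fibre-optic calcium channel with planted transients.

    Signal = 0.1-1 Hz band-limited slow oscillation + half-sine transients
    + white noise. Baseline transients occur at the configured per-minute
    rate (state multipliers allow e.g. elevated IS activity); in addition,
    each spindle independently triggers a transient with probability
    ``coupling_strength`` at a lag uniform in ``coupling_lag_s``. Returns
    the signal and a table of the transients actually planted.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spe = int(round(hyp.epoch_length_s * cfg.rate))
    n = hyp.n_epochs * spe
    total_s = n / cfg.rate

    x = cfg.ca_slow_amp * _band_noise(n, cfg.rate, 0.1, 1.0, rng)
    x = x + cfg.ca_noise_amp * rng.standard_normal(n)

    base_rates = {
        s: cfg.ca_transient_rate_per_min * cfg.ca_state_rate_multiplier.get(s, 1.0)
        for s in _SIM_STATES
    }
    cand: list[tuple[float, float, bool]] = []
    for on, off in _place_events(
        hyp, base_rates, cfg.ca_transient_duration_s, total_s, rng
    ):
        cand.append((on, off, False))
    lag_lo, lag_hi = cfg.coupling_lag_s
    for sp_on in spindles.onsets:
        if rng.uniform() < cfg.coupling_strength:
            on = sp_on + rng.uniform(lag_lo, lag_hi)
            dur = rng.uniform(*cfg.ca_transient_duration_s)
            if on + dur <= total_s:
                cand.append((on, on + dur, True))
    cand.sort()
    rows = []
    last_off = -np.inf
    for on, off, coupled in cand:
        if on < last_off:
            continue
        amp = rng.uniform(*cfg.ca_transient_amp)
        m = int(round((off - on) * cfg.rate))
        a = int(round(on * cfg.rate))
        b = min(a + m, n)
        t = np.arange(b - a) / cfg.rate
        x[a:b] += amp * np.sin(np.pi * t / (off - on))
        rows.append({"onset_s": on, "offset_s": off, "amplitude": amp, "coupled": coupled})
        last_off = off
    ts = TimeSeries(data=x[None, :], rate=cfg.rate, labels=["CA"], units=["dF/F"])
    return ts, pd.DataFrame(rows, columns=["onset_s", "offset_s", "amplitude", "coupled"])


def generate_roi_traces(
    hyp: Hypnogram,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sigma_drive: np.ndarray | None = None,
) -> tuple[ROIMatrix, dict]:
    """Two-photon ROI fluorescence with known pairwise correlation.

    Each ROI is ``loading(state) * common + noise`` scaled onto a positive
    fluorescence baseline, giving theoretical pairwise correlation
    ``rho(state) = loading^2 / (loading^2 + noise_var)``. With
    ``roi_identical`` all ROIs are exact copies. ``sigma_drive`` (a
    per-sample regressor on the ROI grid, e.g. upsampled sigma power) is
    added with per-ROI sign: the first ``roi_frac_positive`` fraction of
    ROIs couples positively, the rest negatively.
    """
    if cfg.n_rois < 2:
        raise ValidationError("need n_rois >= 2")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = int(hyp.duration_s * cfg.roi_rate)
    epoch_idx = np.minimum(
        (np.arange(n) / cfg.roi_rate / hyp.epoch_length_s).astype(int),
        hyp.n_epochs - 1,
    )
    loading = np.array([float(cfg.roi_loading.get(s, 0.0)) for s in hyp.labels])[
        epoch_idx
    ]
    common = rng.standard_normal(n)
    signs = np.where(
        np.arange(cfg.n_rois) < round(cfg.roi_frac_positive * cfg.n_rois), 1.0, -1.0
    )
    if cfg.roi_identical:
        latent = np.tile(loading * common, (cfg.n_rois, 1))
    else:
        latent = loading * common + cfg.roi_noise_sd * rng.standard_normal(
            (cfg.n_rois, n)
        )
    if sigma_drive is not None and cfg.roi_sigma_coupling:
        drive = np.asarray(sigma_drive, float)
        if len(drive) != n:
            raise ValidationError("sigma_drive must be on the ROI sample grid")
        sd = drive.std()
        if sd > 0:
            drive = (drive - drive.mean()) / sd
        latent = latent + cfg.roi_sigma_coupling * signs[:, None] * drive[None, :]
    data = cfg.roi_baseline + cfg.roi_gain * latent
    expected = {
        s: float(l * l / (l * l + cfg.roi_noise_sd**2))
        for s, l in ((s, float(cfg.roi_loading.get(s, 0.0))) for s in _SIM_STATES)
    }
    roi = ROIMatrix(data=data, rate=cfg.roi_rate, is_dff=False)
    return roi, {"expected_corr": expected, "signs": signs}


def generate_spikes(
    hyp: Hypnogram,
    eeg: TimeSeries,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    ff_channel: str = "EEG-FF",
) -> SpikeTrain:
    """Inhomogeneous Poisson spike train phase-locked to delta.

    Instantaneous rate = per-state mean rate x (1 + depth * delta_norm),
    where delta_norm is the 1-4 Hz filtered frontal EEG scaled to unit
    variance; negative rates are clipped at zero (logged). Spikes are drawn
    per sample of the EEG grid.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ff = eeg.channel(ff_channel)
    n = len(ff)
    spe = int(round(hyp.epoch_length_s * eeg.rate))
    epoch_idx = np.minimum(np.arange(n) // spe, hyp.n_epochs - 1)
    state_rate = np.array(
        [float(cfg.spike_state_rate.get(s, 0.0)) for s in hyp.labels]
    )[epoch_idx]
    if cfg.spike_delta_depth:
        delta = bandpass(ff, eeg.rate, 1.0, 4.0)
        sd = delta.std()
        mod = 1.0 + cfg.spike_delta_depth * (delta / sd if sd > 0 else delta)
    else:
        mod = np.ones(n)
    rate = state_rate * mod
    n_neg = int((rate < 0).sum())
    if n_neg:
        logger.warning("clipping %d negative-rate samples to 0", n_neg)
        rate = np.clip(rate, 0.0, None)
    p = rate / eeg.rate
    hits = np.flatnonzero(rng.uniform(size=n) < p)
    times = (hits + 0.5) / eeg.rate
    return SpikeTrain(times_s=times, acquisition_rate=cfg.spike_acquisition_rate)


def simulate_recording(
    cfg: SimConfig, rois: bool = False, spikes: bool = False
) -> SimRecording:
    """Generate a full session: hypnogram, EEG/EMG, calcium, ground truth.

    ROI matrices and spike trains are optional add-ons. A single
    seed-derived random stream drives all stages, so a fixed seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    hyp = generate_hypnogram(cfg, rng)
    eeg, spindle_ann = generate_eeg(hyp, cfg, rng)
    ca, transients = generate_ca_population(hyp, spindle_ann, cfg, rng)
    truth = GroundTruth(
        hypnogram=hyp,
        spindles=spindle_ann,
        ca_transients=transients,
        spike_state_rates=dict(cfg.spike_state_rate),
    )
    rec = SimRecording(
        config=cfg, hypnogram=hyp, eeg=eeg, spindles=spindle_ann, ca=ca, truth=truth
    )
    if rois:
        rec.rois, roi_truth = generate_roi_traces(hyp, cfg, rng)
        truth.roi_expected_corr = roi_truth["expected_corr"]
        truth.roi_signs = roi_truth["signs"]
    if spikes:
        rec.spikes = generate_spikes(hyp, eeg, cfg, rng)
    return rec
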