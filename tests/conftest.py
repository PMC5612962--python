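"""Shared fixtures: simulated sessions are expensive, so the canonical 2-h
recording (and its band-power tables) is computed once per test session."""

from __future__ import annotations

import numpy as np
import pytest

import spindleca as sc


@pytest.fixture(scope="session")
def sim_2h():
    """Default-condition 2-h recording, seed 0, spindle-calcium coupling on."""
    return sc.simulate_recording(sc.SimConfig(seed=0, duration_s=7200.0))


@pytest.fixture(scope="session")
def sim_2h_bandpower(sim_2h):
    """EEG band power (full scheme), calcium slow-band PD, scoring bands
    and epoch EMG power for the canonical recording."""
    rec = sim_2h
    bands = sc.epoch_band_power(
        rec.eeg, sc.DEFAULT_EEG_BANDS, channels=["EEG-FF", "EEG-FP"]
    )
    scoring_bp = sc.epoch_band_power(
        rec.eeg, sc.SCORING_BANDS, channels=["EEG-FF", "EEG-FP"]
    )
    ca = sc.epoch_band_power(rec.ca, {"ca": sc.CA_BAND}, channels=["CA"])
    emg_idx = rec.eeg.labels.index("EMG")
    emg = (sc.slice_epochs(rec.eeg, 4.0)[:, emg_idx, :] ** 2).mean(axis=1)
    return {
        "bands": bands,
        "scoring": scoring_bp,
        "ca_pd": ca.power("CA", "ca").to_numpy(),
        "emg": emg,
    }


def score_pipeline(rec, scoring_bp=None, emg=None):
    """Run the full scorer (epoch rules + IS rule) on a simulated session."""
    if scoring_bp is None:
        scoring_bp = sc.epoch_band_power(
            rec.eeg, sc.SCORING_BANDS, channels=["EEG-FF", "EEG-FP"]
        )
    if emg is None:
        emg_idx = rec.eeg.labels.index("EMG")
        emg = (sc.slice_epochs(rec.eeg, 4.0)[:, emg_idx, :] ** 2).mean(axis=1)
    h = sc.score_epochs(scoring_bp, emg)
    return sc.enforce_is_rule(h, sc.is_candidates(scoring_bp))


def planted_half_sine(durations, rate=200.0, gap_s=8.0, amps=None):
    """Grid-aligned half-sine events on a zero baseline.

    Returns (trace, list of (onset_s, offset_s)). Endpoint samples are
    forced to exactly zero so event support is exactly the stated duration.
    """
    durations = list(durations)
    if amps is None:
        amps = [1.0] * len(durations)
    total = int((gap_s * (len(durations) + 1) + sum(durations)) * rate) + 1
    x = np.zeros(total)
    onsets = []
    t = gap_s
    for d, a in zip(durations, amps):
        i0 = int(round(t * rate))
        m = int(round(d * rate))
        w = a * np.sin(np.pi * np.arange(m + 1) / m)
        w[np.abs(w) < 1e-12] = 0.0
        x[i0 : i0 + m + 1] += w
        onsets.append((t, t + d))
        t += d + gap_s
    return x, onsets


def write_minimal_edf(path, data, rate, labels):
    """Write a minimal EDF file (16-bit, 1-s data records).

    Independent of the package's (mne-based) reader; used as the oracle
    side of the EDF round-trip check.
    """
    data = np.asarray(data, float)
    n_ch, n_samp = data.shape
    spr = int(rate)
    n_rec = n_samp // spr
    pmin, pmax = -1000.0, 1000.0
    dmin, dmax = -32768, 32767

    def pad(s, w):
        return str(s)[:w].ljust(w)

    hdr = b""
    hdr += pad("0", 8).encode()
    hdr += pad("X X X X", 80).encode()  # patient
    hdr += pad("Startdate X X X X", 80).encode()  # recording
    hdr += pad("01.01.20", 8).encode()
    hdr += pad("00.00.00", 8).encode()
    hdr += pad(256 * (1 + n_ch), 8).encode()
    hdr += pad("", 44).encode()
    hdr += pad(n_rec, 8).encode()
    hdr += pad("1", 8).encode()  # record duration s
    hdr += pad(n_ch, 4).encode()
    for lab in labels:
        hdr += pad(lab, 16).encode()
    hdr += b"".join(pad("", 80).encode() for _ in range(n_ch))  # transducer
    hdr += b"".join(pad("uV", 8).encode() for _ in range(n_ch))
    hdr += b"".join(pad(pmin, 8).encode() for _ in range(n_ch))
    hdr += b"".join(pad(pmax, 8).encode() for _ in range(n_ch))
    hdr += b"".join(pad(dmin, 8).encode() for _ in range(n_ch))
    hdr += b"".join(pad(dmax, 8).encode() for _ in range(n_ch))
    hdr += b"".join(pad("", 80).encode() for _ in range(n_ch))  # prefilter
    hdr += b"".join(pad(spr, 8).encode() for _ in range(n_ch))
    hdr += b"".join(pad("", 32).encode() for _ in range(n_ch))
    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                seg = data[c, r * spr : (r + 1) * spr]
                dig = np.round((seg - pmin) * scale + dmin).astype("<i2")
                fh.write(dig.tobytes())
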