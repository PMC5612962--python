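"""Readers and writers for the plain formats used around the analyses.

Signals travel as CSV (header row of channel names, one sample per row, a
leading ``#`` metadata line carrying rate/t0/units), HDF5, or EDF
(read-only, via :mod:`mne`). Hypnograms are one label per line; spindle
annotations, spike times and ROI matrices use small CSV/HDF5 layouts.
All readers round-trip with their writers except EDF, which has no writer.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .core import (
    STATES,
    FormatError,
    Hypnogram,
    ROIMatrix,
    SpikeTrain,
    SpindleAnnotations,
    TimeSeries,
    ValidationError,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_hypnogram",
    "write_hypnogram",
    "read_spindles",
    "write_spindles",
    "read_spiketrain",
    "write_spiketrain",
    "read_roi_matrix",
    "write_roi_matrix",
]

_EXT_FORMAT = {
    ".csv": "csv",
    ".h5": "hdf5",
    ".hdf5": "hdf5",
    ".edf": "edf",
}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _EXT_FORMAT:
        raise FormatError(f"cannot infer format from extension {ext!r}")
    return _EXT_FORMAT[ext]


# -- signals ----------------------------------------------------------------

def _parse_meta_line(line: str) -> dict:
    meta = {}
    for token in line.lstrip("#").strip().split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_timeseries(path, format: str | None = None) -> TimeSeries:
    """Read a multichannel signal from CSV, HDF5 or EDF."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_ts_csv(path)
    if fmt == "hdf5":
        return _read_ts_hdf5(path)
    if fmt == "edf":
        return _read_ts_edf(path)
    raise FormatError(f"unsupported signal format {fmt!r}")


def write_timeseries(ts: TimeSeries, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_ts_csv(ts, path)
    elif fmt == "hdf5":
        _write_ts_hdf5(ts, path)
    elif fmt == "edf":
        raise FormatError("EDF is supported read-only")
    else:
        raise FormatError(f"unsupported signal format {fmt!r}")


def _read_ts_csv(path) -> TimeSeries:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = _parse_meta_line(first)
            header_line = fh.readline()
        else:
            header_line = first
        labels = [c.strip() for c in header_line.rstrip("\n").split(",")]
        n_cols = len(labels)
        rows = []
        for lineno, line in enumerate(fh, start=3 if meta else 2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_cols}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: {err}") from None
    if "rate" not in meta:
        raise FormatError(f"{path}: missing '# rate=' metadata line")
    data = np.asarray(rows, dtype=float).reshape(len(rows), n_cols).T
    units = meta.get("units", "").split(";") if meta.get("units") else None
    if units is not None and len(units) != n_cols:
        units = None
    return TimeSeries(
        data=data,
        rate=float(meta["rate"]),
        labels=labels,
        units=units,
        t0=float(meta.get("t0", 0.0)),
    )


def _write_ts_csv(ts: TimeSeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        units = ";".join(ts.units)
        fh.write(f"# rate={ts.rate!r} t0={ts.t0!r} units={units}\n")
        fh.write(",".join(ts.labels) + "\n")
        for row in ts.data.T:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _read_ts_hdf5(path) -> TimeSeries:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path}: no 'data' dataset")
        d = f["data"]
        return TimeSeries(
            data=d[()],
            rate=float(d.attrs["rate"]),
            labels=[str(x) for x in d.attrs["labels"]],
            units=[str(x) for x in d.attrs["units"]] if "units" in d.attrs else None,
            t0=float(d.attrs.get("t0", 0.0)),
        )


def _write_ts_hdf5(ts: TimeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=ts.data)
        d.attrs["rate"] = ts.rate
        d.attrs["labels"] = ts.labels
        d.attrs["units"] = ts.units
        d.attrs["t0"] = ts.t0


def _read_ts_edf(path) -> TimeSeries:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # mne raises several types for broken files
        raise FormatError(f"{path}: unreadable EDF: {err}") from None
    return TimeSeries(
        data=raw.get_data(),
        rate=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        t0=0.0,
    )


# -- hypnograms -------------------------------------------------------------

def read_hypnogram(path, epoch_length_s: float = 4.0) -> Hypnogram:
    """Read a one-label-per-line hypnogram; unknown labels are rejected."""
    labels = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            lab = line.strip()
            if not lab or lab.startswith("#"):
                continue
            if lab not in STATES:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown state label {lab!r}"
                )
            labels.append(lab)
    return Hypnogram(np.asarray(labels), epoch_length_s=epoch_length_s)


def write_hypnogram(h: Hypnogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab in h.labels:
            fh.write(f"{lab}\n")


# -- spindle annotations ----------------------------------------------------

def read_spindles(path) -> SpindleAnnotations:
    """Read spindle intervals from a CSV with onset_s, offset_s columns."""
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return SpindleAnnotations(df[["onset_s", "offset_s"]].to_numpy(float))


def write_spindles(sp: SpindleAnnotations, path) -> None:
    pd.DataFrame(
        {"onset_s": sp.onsets, "offset_s": sp.offsets}
    ).to_csv(path, index=False)


# -- spike trains -----------------------------------------------------------

def read_spiketrain(path) -> SpikeTrain:
    """Read spike times from a CSV with a time_s column.

    The acquisition rate travels in a ``# acquisition_rate=`` comment line.
    """
    rate = 25000.0
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            rate = float(_parse_meta_line(first).get("acquisition_rate", rate))
            df = pd.read_csv(fh)
        else:
            import io as _io

            df = pd.read_csv(_io.StringIO(first + fh.read()))
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing column 'time_s'")
    return SpikeTrain(df["time_s"].to_numpy(float), acquisition_rate=rate)


def write_spiketrain(st: SpikeTrain, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# acquisition_rate={st.acquisition_rate!r}\n")
        fh.write("time_s\n")
        for t in st.times_s:
            fh.write(f"{float(t)!r}\n")


# -- ROI matrices -----------------------------------------------------------

def read_roi_matrix(path) -> ROIMatrix:
    with h5py.File(path, "r") as f:
        if "rois" not in f:
            raise FormatError(f"{path}: no 'rois' dataset")
        d = f["rois"]
        return ROIMatrix(
            data=d[()],
            rate=float(d.attrs["rate"]),
            roi_ids=[str(x) for x in d.attrs["roi_ids"]],
            is_dff=bool(d.attrs.get("is_dff", False)),
        )


def write_roi_matrix(roi: ROIMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rois", data=roi.data)
        d.attrs["rate"] = roi.rate
        d.attrs["roi_ids"] = roi.roi_ids
        d.attrs["is_dff"] = roi.is_dff
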