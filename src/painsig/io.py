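"""Recording I/O: plain-CSV and OpenSignals-style text, ADC transfer functions.

Recordings come from a wearable acquisition board (single-lead ECG plus a
finger skin-conductance sensor).  Files are either plain CSV in physical
units (mV for ECG, microsiemens for EDA) or OpenSignals-style tab-separated
text carrying raw ADC counts with a JSON header line ("sampling rate",
"resolution", "column").  ADC counts are converted with the vendor transfer
functions (config-overridable constants).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: vendor transfer constants (overridable per call)
DEFAULT_VCC = 3.3          # supply voltage, V
EDA_DIVISOR_US = 0.132     # sensor transfer divisor, converts V -> uS
ECG_GAIN = 1100.0          # ECG sensor amplifier gain

MIN_SEGMENT_S = 10.0       # minimum usable channel duration

VALID_UNITS = {"uS", "mV", "adc"}
#: default physical units by channel name
CHANNEL_UNITS = {"ecg": "mV", "eda": "uS"}


class RecordingError(ValueError):
    """Raised for malformed or unusable recording files."""


@dataclass
class SignalChannel:
    """A uniformly sampled signal channel.

    Parameters
    ----------
    samples : array of float
    fs : sampling rate, Hz
    units : one of ``{"uS", "mV", "adc"}``
    n_bits : ADC resolution, required when ``units == "adc"``
    """

    samples: np.ndarray
    fs: float
    units: str
    n_bits: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise RecordingError(f"fs must be positive, got {self.fs}")
        if self.units not in VALID_UNITS:
            raise RecordingError(f"unknown units {self.units!r}, expected one of {sorted(VALID_UNITS)}")
        if self.units == "adc" and self.n_bits is None:
            raise RecordingError("adc channel requires n_bits")
        if np.isnan(self.samples).any():
            raise RecordingError("channel contains NaN samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def require_min_length(self) -> None:
        if self.duration_s < MIN_SEGMENT_S:
            raise RecordingError(
                f"channel duration {self.duration_s:.2f}s below minimum usable "
                f"segment of {MIN_SEGMENT_S:.0f}s")


@dataclass
class Recording:
    """One patient's synchronized recording (ECG and/or EDA channels)."""

    patient_id: str
    channels: dict[str, SignalChannel] = field(default_factory=dict)

    def require(self, name: str) -> SignalChannel:
        if name not in self.channels:
            raise RecordingError(f"recording {self.patient_id!r} lacks channel {name!r}")
        return self.channels[name]

    @property
    def duration_s(self) -> float:
        return min(ch.duration_s for ch in self.channels.values())


# ---------------------------------------------------------------------------
# ADC transfer functions
# ---------------------------------------------------------------------------

def _check_raw(raw: np.ndarray, n_bits: int) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    top = 2 ** n_bits - 1
    if raw.size and (raw.min() < 0 or raw.max() > top):
        raise ValueError(f"raw ADC counts outside [0, {top}] for n_bits={n_bits}")
    return raw


def adc_to_microsiemens(raw, n_bits: int = 10, vcc: float = DEFAULT_VCC,
                        divisor: float = EDA_DIVISOR_US) -> np.ndarray:
    """EDA transfer: ``uS = ((raw / 2^n) * vcc) / divisor``."""
    raw = _check_raw(raw, n_bits)
    return (raw / 2 ** n_bits) * vcc / divisor


def adc_to_millivolts(raw, n_bits: int = 10, vcc: float = DEFAULT_VCC,
                      gain: float = ECG_GAIN) -> np.ndarray:
    """ECG transfer: ``mV = ((raw / 2^n - 1/2) * vcc) / gain * 1000``."""
    raw = _check_raw(raw, n_bits)
    return (raw / 2 ** n_bits - 0.5) * vcc / gain * 1000.0


def microsiemens_to_adc(us, n_bits: int = 10, vcc: float = DEFAULT_VCC,
                        divisor: float = EDA_DIVISOR_US) -> np.ndarray:
    counts = np.asarray(us, dtype=float) * divisor / vcc * 2 ** n_bits
    return np.clip(np.round(counts), 0, 2 ** n_bits - 1).astype(int)


def millivolts_to_adc(mv, n_bits: int = 10, vcc: float = DEFAULT_VCC,
                      gain: float = ECG_GAIN) -> np.ndarray:
    counts = (np.asarray(mv, dtype=float) / 1000.0 * gain / vcc + 0.5) * 2 ** n_bits
    return np.clip(np.round(counts), 0, 2 ** n_bits - 1).astype(int)


def convert_channel(channel: SignalChannel, name: str, vcc: float = DEFAULT_VCC) -> SignalChannel:
    """Convert an ``adc`` channel to physical units based on its name."""
    if channel.units != "adc":
        return channel
    if name == "eda":
        return SignalChannel(adc_to_microsiemens(channel.samples, channel.n_bits, vcc),
                             channel.fs, "uS")
    if name == "ecg":
        return SignalChannel(adc_to_millivolts(channel.samples, channel.n_bits, vcc),
                             channel.fs, "mV")
    raise RecordingError(f"no ADC transfer function for channel {name!r}")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_COL_RE = re.compile(r"^\s*(?P<name>[A-Za-z_]+)\s*(?:\((?P<units>[^)]+)\))?\s*$")


def _parse_column(col: str) -> tuple[str, str | None]:
    m = _COL_RE.match(col)
    if m is None:
        raise RecordingError(f"cannot parse column name {col!r}")
    units = m.group("units")
    if units is not None:
        units = units.replace("µ", "u")
    return m.group("name").lower(), units


def read_recording(path, format: str = "csv", patient_id: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read one recording file.

    Parameters
    ----------
    path : file path
    format : ``"csv"`` (physical units, optional time column) or
        ``"opensignals"`` (tab-separated ADC counts with a ``#`` header).
    patient_id : defaults to the file stem (channel suffixes stripped).
    fs : sampling rate, required for CSV files without a time column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in {"csv", "opensignals"}:
        raise ValueError(f"unknown format {format!r}")
    if patient_id is None:
        patient_id = re.sub(r"_(ecg|eda)$", "", path.stem)
    if format == "csv":
        return _read_csv(path, patient_id, fs)
    return _read_opensignals(path, patient_id)


def _infer_fs(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0 or np.any(dt <= 0):
        raise RecordingError("non-monotonic or degenerate time column")
    if (dt.max() - dt.min()) > 0.01 * dt.mean():
        raise RecordingError("time column not uniform within 1% (irregular sampling unsupported)")
    return 1.0 / dt.mean()


def _read_csv(path: Path, patient_id: str, fs: float | None) -> Recording:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RecordingError(f"empty recording file {path}") from exc
    if df.empty:
        raise RecordingError(f"recording file {path} contains no samples")
    cols = [(_parse_column(c), c) for c in df.columns]
    time_col = next((orig for (name, _), orig in cols if name in {"time", "t"}), None)
    if time_col is not None:
        fs_eff = _infer_fs(df[time_col].to_numpy(dtype=float))
    elif fs is not None:
        fs_eff = fs
    else:
        raise RecordingError(f"{path} has no time column; pass fs explicitly")
    channels: dict[str, SignalChannel] = {}
    for (name, units), orig in cols:
        if name in {"time", "t"}:
            continue
        if name not in CHANNEL_UNITS:
            raise RecordingError(f"unexpected channel column {orig!r} in {path}")
        units = units or CHANNEL_UNITS[name]
        if units not in VALID_UNITS:
            raise RecordingError(f"unknown units {units!r} for column {orig!r}")
        values = df[orig].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise RecordingError(f"NaN samples in column {orig!r} of {path}")
        channels[name] = SignalChannel(values, fs_eff, units)
    if not channels:
        raise RecordingError(f"no channel columns (ecg/eda) found in {path}")
    return Recording(patient_id, channels)


def _read_opensignals(path: Path, patient_id: str) -> Recording:
    header: dict | None = None
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("{"):
                    try:
                        header = json.loads(body)
                    except json.JSONDecodeError as exc:
                        raise RecordingError(f"unparseable OpenSignals header in {path}") from exc
            elif line.strip():
                data_lines.append(line)
    if header is None:
        raise RecordingError(f"no JSON header found in OpenSignals file {path}")
    if not data_lines:
        raise RecordingError(f"OpenSignals file {path} contains no samples")
    # header may be nested under a device key
    if "sampling rate" not in header:
        for value in header.values():
            if isinstance(value, dict) and "sampling rate" in value:
                header = value
                break
    try:
        fs = float(header["sampling rate"])
        columns = [str(c).lower() for c in header["column"]]
        resolution = header["resolution"]
    except KeyError as exc:
        raise RecordingError(f"OpenSignals header in {path} missing {exc}") from exc
    rows = np.array([ln.split("\t") for ln in data_lines], dtype=float)
    if rows.shape[1] != len(columns):
        raise RecordingError(f"column count mismatch in {path}")
    sig_cols = [i for i, c in enumerate(columns) if c in CHANNEL_UNITS]
    if not sig_cols:
        raise RecordingError(f"no ecg/eda columns declared in {path}")
    channels = {}
    for j, i in enumerate(sig_cols):
        n_bits = int(resolution[j] if isinstance(resolution, Sequence) else resolution)
        channels[columns[i]] = SignalChannel(rows[:, i], fs, "adc", n_bits=n_bits)
    return Recording(patient_id, channels)


def write_recording_csv(recording: Recording, directory) -> dict[str, Path]:
    """Write each channel as ``<patient_id>_<channel>.csv`` (time + values).

    Channels sampled at different rates cannot share one time column, so one
    file per channel is written.  Returns the mapping channel -> path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ch in recording.channels.items():
        if ch.units == "adc":
            raise RecordingError("convert adc channels to physical units before writing CSV")
        t = np.arange(len(ch.samples)) / ch.fs
        df = pd.DataFrame({"time": t, f"{name}({ch.units})": ch.samples})
        out = directory / f"{recording.patient_id}_{name}.csv"
        df.to_csv(out, index=False, float_format="%.12g")
        paths[name] = out
    return paths


def read_patient_csv(paths: Iterable, patient_id: str | None = None) -> Recording:
    """Read and merge per-channel CSV files into one Recording."""
    recs = [read_recording(p, "csv", patient_id=patient_id) for p in paths]
    if not recs:
        raise RecordingError("no paths given")
    merged = Recording(recs[0].patient_id, {})
    for rec in recs:
        merged.channels.update(rec.channels)
    return merged


def write_opensignals(recording: Recording, path, vcc: float = DEFAULT_VCC,
                      n_bits: int = 10) -> Path:
    """Write an OpenSignals-style tab-separated file (ADC counts, JSON header).

    All channels must share one sampling rate (the board acquires that way).
    """
    path = Path(path)
    fss = {ch.fs for ch in recording.channels.values()}
    if len(fss) != 1:
        raise RecordingError("OpenSignals writer requires a single sampling rate across channels")
    fs = fss.pop()
    names = list(recording.channels)
    cols = []
    for name in names:
        ch = recording.channels[name]
        if ch.units == "uS":
            cols.append(microsiemens_to_adc(ch.samples, n_bits, vcc))
        elif ch.units == "mV":
            cols.append(millivolts_to_adc(ch.samples, n_bits, vcc, ECG_GAIN))
        else:
            cols.append(np.asarray(ch.samples, dtype=int))
    n = min(len(c) for c in cols)
    header = {
        "device": "synthetic",
        "sampling rate": fs,
        "resolution": [n_bits] * len(names),
        "column": ["nSeq"] + names,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# OpenSignals Text File Format\n")
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("# EndOfHeader\n")
        for i in range(n):
            fields = [str(i)] + [str(int(c[i])) for c in cols]
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# Cohort-level helpers
# ---------------------------------------------------------------------------

def trim_to_common_length(recordings: Sequence[Recording]) -> list[Recording]:
    """Truncate every channel (from the end) to the shortest recording.

    Recording onset is the only shared anchor across patients, so the start
    is kept and the tail dropped.  Raises if the resulting duration violates
    the minimum usable segment length.
    """
    if len(recordings) == 0:
        raise ValueError("empty recording set")
    d_min = min(rec.duration_s for rec in recordings)
    if d_min < MIN_SEGMENT_S:
        raise RecordingError(
            f"shortest recording ({d_min:.2f}s) below minimum usable segment of "
            f"{MIN_SEGMENT_S:.0f}s")
    out = []
    for rec in recordings:
        channels = {}
        for name, ch in rec.channels.items():
            n_keep = int(round(d_min * ch.fs))
            channels[name] = SignalChannel(ch.samples[:n_keep], ch.fs, ch.units, ch.n_bits)
        out.append(Recording(rec.patient_id, channels))
    return out
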