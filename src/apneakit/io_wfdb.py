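"""Reading and writing single-lead ECG recordings with per-minute apnea labels.

Two on-disk layouts are supported:

* A minimal subset of the PhysioNet WFDB conventions used by the Apnea-ECG
  database: a ``.hea`` header, a format-16 (16-bit little-endian) ``.dat``
  signal file and a ``.apn`` annotation file in the MIT annotation format
  with one label ('N' or 'A') on every minute boundary.
* A plain-text CSV fallback (one sample value per line, plus a separate
  label file with one label per line) for quick inspection and for
  environments where binary files are unwelcome.

Labels follow the database's two-letter alphabet: ``N`` (normal minute) and
``A`` (minute containing apnea/hypopnea).  Label ``i`` covers the half-open
sample window ``[i*60*fs, (i+1)*60*fs)``; a trailing partial minute is
discarded.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ECGRecording",
    "FormatError",
    "read_recording",
    "write_recording",
]

VALID_LABELS = frozenset({"N", "A"})

#: MIT annotation codes used by the Apnea-ECG apnea annotations.
_CODE_TO_SYMBOL = {1: "N", 8: "A"}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

_SKIP = 59  # pseudo-annotation: long interval in following 4 bytes
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


class FormatError(ValueError):
    """A file violates the expected WFDB/CSV conventions."""


@dataclass
class ECGRecording:
    """A single-lead ECG signal with one label per whole minute.

    Parameters
    ----------
    record_id:
        Name of the record (also the file stem on disk).
    fs:
        Sampling rate in Hz; the Apnea-ECG database uses 100 Hz.
    signal:
        1-D amplitude sequence (mV for database records, arbitrary units
        for synthetic ones).
    minute_labels:
        One symbol from ``{'N', 'A'}`` per whole minute of signal.
    reference_ahi:
        Optional reference apnea-hypopnea index (events/hour) from the
        source database (e.g. the PSG-derived value).
    """

    record_id: str
    fs: float
    signal: np.ndarray
    minute_labels: Sequence[str]
    reference_ahi: Optional[float] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        self.minute_labels = list(self.minute_labels)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = set(self.minute_labels) - VALID_LABELS
        if bad:
            raise FormatError(
                f"invalid annotation symbol(s) {sorted(bad)}; expected one of "
                f"{sorted(VALID_LABELS)}"
            )
        n_whole = int(len(self.signal) // self.samples_per_minute)
        if len(self.minute_labels) != n_whole:
            raise ValueError(
                f"{len(self.minute_labels)} labels for {n_whole} whole minutes "
                f"of signal ({len(self.signal)} samples at {self.fs} Hz)"
            )

    @property
    def samples_per_minute(self) -> int:
        return int(round(60 * self.fs))

    @property
    def n_minutes(self) -> int:
        return len(self.minute_labels)

    @property
    def n_apnea_minutes(self) -> int:
        return sum(1 for s in self.minute_labels if s == "A")

    @property
    def annotation_ahi(self) -> float:
        """AHI implied by the annotations themselves: 60*N_A/L events/hour."""
        return 60.0 * self.n_apnea_minutes / self.n_minutes

    def minute(self, i: int) -> np.ndarray:
        """Samples of minute ``i`` (half-open window, 0-based)."""
        spm = self.samples_per_minute
        if not 0 <= i < self.n_minutes:
            raise IndexError(f"minute {i} out of range [0, {self.n_minutes})")
        return self.signal[i * spm : (i + 1) * spm]

    @classmethod
    def from_parts(
        cls,
        record_id: str,
        fs: float,
        signal: np.ndarray,
        minute_labels: Sequence[str],
        reference_ahi: Optional[float] = None,
    ) -> "ECGRecording":
        """Build a recording, reconciling label count and signal length.

        A trailing partial minute of signal is discarded; if the label count
        and the whole-minute count disagree, both are truncated to the
        shorter (the database occasionally differs by one minute).
        """
        signal = np.asarray(signal, dtype=float).ravel()
        spm = int(round(60 * fs))
        n_whole = len(signal) // spm
        n = min(n_whole, len(minute_labels))
        return cls(record_id, fs, signal[: n * spm], list(minute_labels)[:n],
                   reference_ahi)


# ---------------------------------------------------------------------------
# WFDB subset
# ---------------------------------------------------------------------------

def _write_header(path: Path, record_id: str, fs: float, n_samples: int,
                  gain: float, first: int, checksum: int) -> None:
    lines = [
        f"{record_id} 1 {fs:g} {n_samples}",
        f"{record_id}.dat 16 {gain:g}/mV 16 0 {first} {checksum} 0 ECG",
    ]
    path.write_text("\n".join(lines) + "\n")


def _parse_header(path: Path) -> dict:
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise FormatError(f"{path}: header needs a record and a signal line")
    rec = lines[0].split()
    sig = lines[1].split()
    if len(rec) < 3:
        raise FormatError(f"{path}: malformed record line {lines[0]!r}")
    info = {
        "record_id": rec[0],
        "n_sig": int(rec[1]),
        "fs": float(rec[2]),
        "n_samples": int(rec[3]) if len(rec) > 3 else None,
        "dat_file": sig[0],
        "fmt": sig[1],
    }
    if info["n_sig"] != 1:
        raise FormatError(f"{path}: only single-signal records are supported")
    if info["fmt"] != "16":
        raise FormatError(f"{path}: unsupported signal format {info['fmt']!r}")
    gain_field = sig[2] if len(sig) > 2 else "200"
    gain_field = gain_field.split("/")[0]
    baseline = 0.0
    if "(" in gain_field:
        gain_field, rest = gain_field.split("(")
        baseline = float(rest.rstrip(")"))
    info["gain"] = float(gain_field) or 200.0
    info["baseline"] = baseline
    return info


def _read_mit_annotations(path: Path, fs: float) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file into (sample_time, symbol) pairs."""
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:  # end of annotations
            break
        if code == _SKIP and interval == 0:
            if i + 4 > len(data):
                raise FormatError(f"{path}: truncated SKIP annotation")
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            val = (high << 16) | low
            if val >= 1 << 31:
                val -= 1 << 32
            pending_skip += val
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        t += pending_skip + interval
        pending_skip = 0
        symbol = _CODE_TO_SYMBOL.get(code)
        if symbol is None:
            raise FormatError(
                f"{path}: annotation code {code} at sample {t} is not one of "
                f"the apnea symbols {sorted(VALID_LABELS)}"
            )
        out.append((t, symbol))
    return out


def _write_mit_annotations(path: Path, labels: Sequence[str], spm: int) -> None:
    buf = bytearray()
    prev = 0
    for i, sym in enumerate(labels):
        t = i * spm
        delta = t - prev
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (_SYMBOL_TO_CODE[sym] << 10) | delta)
        prev = t
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))


def _labels_from_annotations(ann: list[tuple[int, str]], spm: int,
                             path: Path) -> list[str]:
    labels: list[str] = []
    for t, sym in ann:
        if t % spm != 0:
            raise FormatError(
                f"{path}: annotation at sample {t} is not on a minute boundary"
            )
        minute = t // spm
        if minute != len(labels):
            raise FormatError(
                f"{path}: annotations are not consecutive per-minute "
                f"(expected minute {len(labels)}, got {minute})"
            )
        labels.append(sym)
    return labels


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_recording(signal_path, annotation_path,
                   reference_ahi: Optional[float] = None) -> ECGRecording:
    """Read a recording from WFDB-style or CSV files.

    ``signal_path`` ending in ``.hea`` selects the WFDB layout (the ``.dat``
    file named in the header is read from the same directory); any other
    extension selects the CSV fallback.  ``annotation_path`` is the ``.apn``
    (or label text) file.  A sampling rate other than 100 Hz triggers a
    warning; no resampling is performed.
    """
    signal_path = Path(signal_path)
    annotation_path = Path(annotation_path)
    for p in (signal_path, annotation_path):
        if not p.exists():
            raise FileNotFoundError(p)

    if signal_path.suffix == ".hea":
        info = _parse_header(signal_path)
        fs = info["fs"]
        raw = np.fromfile(signal_path.with_name(info["dat_file"]),
                          dtype="<i2").astype(float)
        signal = (raw - info["baseline"]) / info["gain"]
        record_id = info["record_id"]
        spm = int(round(60 * fs))
        labels = _labels_from_annotations(
            _read_mit_annotations(annotation_path, fs), spm, annotation_path)
    else:
        fs = 100.0
        values = []
        for ln in signal_path.read_text().splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                if "fs=" in ln:
                    fs = float(ln.split("fs=")[1])
                continue
            values.append(float(ln))
        signal = np.asarray(values)
        labels = []
        for ln in annotation_path.read_text().splitlines():
            ln = ln.strip()
            if ln and not ln.startswith("#"):
                if ln not in VALID_LABELS:
                    raise FormatError(
                        f"{annotation_path}: invalid annotation symbol {ln!r}")
                labels.append(ln)
        record_id = signal_path.stem

    if fs != 100.0:
        warnings.warn(
            f"{record_id}: sampling rate is {fs:g} Hz, not the expected "
            "100 Hz; proceeding without resampling", stacklevel=2)
    return ECGRecording.from_parts(record_id, fs, signal, labels,
                                   reference_ahi=reference_ahi)


def write_recording(rec: ECGRecording, out_dir, fmt: str = "wfdb",
                    gain: float = 200.0) -> tuple[Path, Path]:
    """Write a recording; returns (signal_path, annotation_path).

    ``fmt='wfdb'`` writes ``<id>.hea`` + ``<id>.dat`` + ``<id>.apn``
    (signal quantized to 16 bits at the given gain in adu/mV);
    ``fmt='csv'`` writes ``<id>.csv`` + ``<id>.labels``.
    """
    if rec.signal.size == 0:
        raise ValueError("refusing to write an empty signal")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e

    if fmt == "wfdb":
        raw = np.clip(np.round(rec.signal * gain), -32768, 32767).astype("<i2")
        dat = out_dir / f"{rec.record_id}.dat"
        raw.tofile(dat)
        hea = out_dir / f"{rec.record_id}.hea"
        checksum = int(np.sum(raw.astype(np.int64)) & 0xFFFF)
        if checksum >= 0x8000:
            checksum -= 0x10000
        _write_header(hea, rec.record_id, rec.fs, raw.size, gain,
                      int(raw[0]), checksum)
        apn = out_dir / f"{rec.record_id}.apn"
        _write_mit_annotations(apn, rec.minute_labels, rec.samples_per_minute)
        return hea, apn
    if fmt == "csv":
        sig = out_dir / f"{rec.record_id}.csv"
        lines = [f"# fs={rec.fs:g}"] + [f"{v:.6f}" for v in rec.signal]
        sig.write_text("\n".join(lines) + "\n")
        lab = out_dir / f"{rec.record_id}.labels"
        lab.write_text("\n".join(rec.minute_labels) + "\n")
        return sig, lab
    raise ValueError(f"unknown format {fmt!r}; use 'wfdb' or 'csv'")
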