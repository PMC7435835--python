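"""Per-minute ECG conditioning: Butterworth bandpass filtering and z-scoring.

Each 1-minute window (6000 samples at 100 Hz) is filtered through a 4-pole
digital Butterworth bandpass (0.5-15 Hz by default) to remove baseline
wander and high-frequency interference, then standardized to zero mean and
unit standard deviation.  Filtering is causal (a direct-form recurrence with
zero initial conditions) and applied per minute, so minutes are processed
independently of each other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io_wfdb import ECGRecording

__all__ = [
    "FilterCoefficients",
    "MinuteSegment",
    "DegenerateSegmentWarning",
    "design_bandpass",
    "apply_filter",
    "zscore",
    "preprocess_recording",
]


class DegenerateSegmentWarning(UserWarning):
    """A segment had zero variance and was standardized to all zeros."""


@dataclass(frozen=True)
class FilterCoefficients:
    """Transfer-function coefficients of a 4-pole digital bandpass.

    ``b`` are the feedforward (numerator) and ``a`` the feedback
    (denominator) coefficients of

        y(n) = sum_k b[k] x(n-k) - sum_{k>=1} a[k] y(n-k),

    with ``a[0] == 1``.  A true bandpass has zero gain at DC (z=1) and at
    the Nyquist frequency (z=-1); both are checked on construction.
    """

    b: tuple
    a: tuple
    fs: float
    passband: tuple

    def __post_init__(self):
        b, a = np.asarray(self.b, float), np.asarray(self.a, float)
        if len(b) != 5 or len(a) != 5:
            raise ValueError("expected 5 numerator and 5 denominator "
                             f"coefficients, got {len(b)}/{len(a)}")
        if abs(a[0] - 1.0) > 1e-12:
            raise ValueError("denominator must be normalized (a[0] == 1)")
        for z in (1.0, -1.0):
            gain = abs(np.polyval(b, z) / np.polyval(a, z))
            if gain > 1e-6:
                raise ValueError(
                    f"not a bandpass: |H({z:+.0f})| = {gain:.2e} exceeds 1e-6")

    def response_at(self, freq_hz: float) -> complex:
        """Frequency response H(e^{j 2 pi f / fs})."""
        w = 2 * np.pi * freq_hz / self.fs
        z = np.exp(1j * w)
        return np.polyval(self.b, z) / np.polyval(self.a, z)

    def to_json(self) -> str:
        return json.dumps({
            "b": list(self.b), "a": list(self.a),
            "fs_hz": self.fs, "passband_hz": list(self.passband),
        }, indent=2)


@dataclass
class MinuteSegment:
    """One preprocessed 1-minute window paired with its label."""

    values: np.ndarray           # 60*fs standardized samples
    label: str                   # 'N' or 'A'
    source_record: str
    minute_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.label not in ("N", "A"):
            raise ValueError(f"label must be 'N' or 'A', got {self.label!r}")
        if self.minute_index < 0:
            raise ValueError("minute_index must be non-negative")


def design_bandpass(fs: float, low: float, high: float) -> FilterCoefficients:
    """Design the 4-pole digital Butterworth bandpass via bilinear transform.

    At the reference settings (fs=100, 0.5-15 Hz) the numerator is
    b0*[1, 0, -2, 0, 1] with b0 = 0.1242 to four decimals.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got "
            f"low={low}, high={high}, fs={fs}")
    # a 4-pole bandpass is an order-2 lowpass prototype warped to the band
    b, a = sps.butter(2, [low, high], btype="bandpass", fs=fs)
    return FilterCoefficients(tuple(b), tuple(a), fs, (low, high))


def apply_filter(x: Sequence[float], c: FilterCoefficients) -> np.ndarray:
    """Causal direct-form filtering with zero initial conditions."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("input must contain at least one sample")
    return sps.lfilter(c.b, c.a, x)


def zscore(x: Sequence[float]) -> np.ndarray:
    """Standardize to zero mean, unit standard deviation (population sd).

    A zero-variance input returns all zeros with a DegenerateSegmentWarning
    so one flat-line minute cannot abort a whole-recording run.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    mu = x.mean()
    sd = x.std()  # population convention (divide by n)
    if sd == 0:
        warnings.warn("zero-variance segment standardized to zeros",
                      DegenerateSegmentWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - mu) / sd


def preprocess_recording(rec: ECGRecording,
                         coeffs: FilterCoefficients | None = None
                         ) -> list[MinuteSegment]:
    """Filter and standardize every whole minute of a recording.

    Each minute is processed independently: bandpass filtered (zero initial
    conditions) and then z-scored, preserving its label.
    """
    if coeffs is None:
        coeffs = design_bandpass(rec.fs, 0.5, 15.0)
    segments = []
    for i in range(rec.n_minutes):
        try:
            filtered = apply_filter(rec.minute(i), coeffs)
            standardized = zscore(filtered)
        except Exception as e:
            raise RuntimeError(
                f"preprocessing failed for record {rec.record_id!r} "
                f"minute {i}: {e}") from e
        segments.append(MinuteSegment(standardized, rec.minute_labels[i],
                                      rec.record_id, i))
    return segments
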