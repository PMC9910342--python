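"""Physical-unit signal containers, sensor calibration, resampling and alignment.

All lab channels are carried as :class:`CalibratedSignal` objects in their
physical units (microphone in Pa, oral airflow in mL/s, intraoral pressure in
cm H2O, accelerometer in cm/s^2).  Raw acquisition is a voltage series; an
affine :class:`CalibrationLine` (units per volt, offset in units) maps it to
physical units.  Time indexing is 0-based sample index with half-open
``[start, end)`` intervals throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import AlignmentUndefinedError, DegenerateFitError, InvalidCalibrationError

LAB_FS = 20000.0
AMBULATORY_FS = 11025.0

#: maximum alignment offset searched by :func:`align_acc_to_mic`
MAX_ALIGN_LAG_S = 1.0


class Channel(str, Enum):
    MIC = "MIC"
    FLOW = "FLOW"
    IOP = "IOP"
    ACC = "ACC"


CHANNEL_UNITS = {
    Channel.MIC: "Pa",
    Channel.FLOW: "mL/s",
    Channel.IOP: "cmH2O",
    Channel.ACC: "cm/s2",
}


@dataclass
class CalibratedSignal:
    """A uniformly sampled time series in physical units.

    Parameters
    ----------
    samples : ndarray
        Signal values in `units`.
    fs : float
        Sampling rate in Hz (> 0).
    channel : Channel
        Which sensor this series came from.
    units : str, optional
        Physical units; defaults to the canonical units for `channel`.
    """

    samples: np.ndarray
    fs: float
    channel: Channel
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel = Channel(self.channel)
        if not self.units:
            self.units = CHANNEL_UNITS[self.channel]
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def slice(self, start: int, end: int) -> "CalibratedSignal":
        """Return the half-open sample interval ``[start, end)``."""
        return CalibratedSignal(self.samples[start:end], self.fs, self.channel, self.units)


@dataclass(frozen=True)
class CalibrationLine:
    """Affine voltage-to-units map: ``units = slope * volts + intercept``."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InvalidCalibrationError("calibration slope must be nonzero")


def apply_calibration(
    raw: np.ndarray,
    line: CalibrationLine,
    fs: float,
    channel: Channel,
) -> CalibratedSignal:
    """Map a raw voltage series to physical units with an affine line."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw voltage series must be finite")
    return CalibratedSignal(line.slope * raw + line.intercept, fs, channel)


def fit_calibration_line(
    known_inputs: np.ndarray, measured_voltages: np.ndarray
) -> CalibrationLine:
    """Least-squares line through (voltage, known physical value) points.

    With exactly two distinct points the line interpolates them exactly.
    """
    y = np.asarray(known_inputs, dtype=float)
    v = np.asarray(measured_voltages, dtype=float)
    if len(y) < 2 or len(v) != len(y):
        raise ValueError("need >= 2 paired calibration points")
    if np.ptp(v) == 0:
        raise DegenerateFitError("all calibration voltages identical")
    slope, intercept = np.polyfit(v, y, 1)
    return CalibrationLine(slope=float(slope), intercept=float(intercept))


def resample(sig: CalibratedSignal, target_fs: float) -> CalibratedSignal:
    """Band-limited polyphase resampling to `target_fs`.

    Uses the exact rational rate (11025 -> 20000 is 800/441), so long
    recordings accumulate no drift.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be > 0")
    if target_fs == sig.fs:
        return sig
    ratio = Fraction(target_fs / sig.fs).limit_denominator(10_000)
    out = sps.resample_poly(sig.samples, ratio.numerator, ratio.denominator,
                            window=("kaiser", 12.0))
    return CalibratedSignal(out, target_fs, sig.channel, sig.units)


def align_acc_to_mic(
    acc: CalibratedSignal,
    mic: CalibratedSignal,
    max_lag_s: float = MAX_ALIGN_LAG_S,
) -> int:
    """Integer sample lag of `acc` relative to `mic` by cross-correlation.

    A positive returned lag k means ``acc[n] ~ mic[n - k]`` (the ACC channel
    started k samples later); advancing `acc` by k samples aligns the two.
    The search is bounded to +/- `max_lag_s` seconds.
    """
    if acc.fs != mic.fs:
        raise ValueError("acc and mic must share a sampling rate; resample first")
    a = acc.samples - np.mean(acc.samples)
    m = mic.samples - np.mean(mic.samples)
    if not np.any(a) or not np.any(m):
        raise AlignmentUndefinedError("zero-energy input; alignment undefined")
    c = sps.correlate(a, m, mode="full", method="fft")
    lags = sps.correlation_lags(len(a), len(m), mode="full")
    max_lag = int(round(max_lag_s * acc.fs))
    keep = np.abs(lags) <= max_lag
    return int(lags[keep][np.argmax(c[keep])])


# ---------------------------------------------------------------------------
# WAV + sidecar JSON persistence
# ---------------------------------------------------------------------------

@dataclass
class SignalMeta:
    channel: Channel
    units: str
    fs: float
    calibration: CalibrationLine | None = field(default=None)


def save_signal(path: str | Path, sig: CalibratedSignal) -> Path:
    """Write a float32 WAV plus a sidecar JSON describing channel and units."""
    path = Path(path)
    wavfile.write(path, int(round(sig.fs)), sig.samples.astype(np.float32))
    meta = {"channel": sig.channel.value, "units": sig.units, "fs": sig.fs}
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_signal(path: str | Path) -> CalibratedSignal:
    """Read a WAV written by :func:`save_signal` (or any PCM/float WAV)."""
    path = Path(path)
    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return CalibratedSignal(data, float(meta.get("fs", fs)),
                                Channel(meta["channel"]), meta.get("units", ""))
    return CalibratedSignal(data, float(fs), Channel.ACC)
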