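"""Frame-level scalar features from accelerometer and microphone signals.

Implements the measures that feed both the laboratory models and the
ambulatory voice-activity detector: RMS magnitude, autocorrelation-based
fundamental frequency with octave-error (subharmonic) correction, cepstral
peak prominence, sound pressure level at the 15-cm reference distance, the
low/high spectral power ratio, and the log-log ACC-level -> SPL mapping used
when no microphone is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft
from scipy.signal import get_window

from .errors import DegenerateFitError, UndefinedSplError, UnvoicedFrameError

#: SPL reference pressure (Pa)
P_REF = 20e-6
#: ACC level reference (cm/s^2) for the dB re 1 cm/s^2 scale
ACC_REF = 1.0

DEFAULT_FMIN = 70.0
DEFAULT_FMAX = 1000.0
SUBHARMONIC_THRESHOLD = 0.25
#: autocorrelation peaks below this are treated as aperiodic (unvoiced)
VOICING_FLOOR = 0.30


@dataclass
class FrameFeatures:
    """Scalar features of one analysis window (vowel middle or 50-ms frame)."""

    rms: float                       # cm/s^2 (ACC) or window units
    f0: float                        # Hz; NaN when unvoiced
    cpp: float                       # dB
    spl: float                       # dB SPL @ 15 cm
    autocorr_peak: float             # [0, 1]
    subharmonic_peak: float          # [0, 1]; NaN when no secondary peak exists
    lh_ratio: float                  # dB, low(<2 kHz) minus high(>2 kHz) power


@dataclass
class SplMapping:
    """Log-log line mapping ACC level (dB re 1 cm/s^2) to dB SPL @ 15 cm."""

    slope: float
    intercept: float
    reliable: bool = True


def middle_window(x: np.ndarray, fs: float, duration: float = 0.050) -> np.ndarray:
    """Middle `duration` seconds of `x` (the whole window if shorter)."""
    n = int(round(duration * fs))
    if len(x) <= n:
        return np.asarray(x)
    start = (len(x) - n) // 2
    return np.asarray(x)[start: start + n]


def frame_rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x**2)))


def spl_from_mic(mic_window: np.ndarray) -> float:
    """20*log10(rms / 20 uPa); the microphone sits 15 cm from the lips."""
    rms = frame_rms(mic_window)
    if rms <= 0:
        raise UndefinedSplError("zero-energy microphone window")
    return 20.0 * math.log10(rms / P_REF)


def acc_level_db(acc_rms: float) -> float:
    """ACC RMS magnitude on the dB re 1 cm/s^2 scale."""
    if acc_rms <= 0:
        raise ValueError("acc_rms must be > 0")
    return 20.0 * math.log10(acc_rms / ACC_REF)


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through samples (i-1, i, i+1); (offset, value)."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0, float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0, float(b)
    d = 0.5 * (a - c) / denom
    return float(d), float(b - 0.25 * (a - c) * d)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1


def f0_autocorrelation(
    window: np.ndarray,
    fs: float,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    subharmonic_threshold: float = SUBHARMONIC_THRESHOLD,
    voicing_floor: float = VOICING_FLOOR,
) -> tuple[float, float, float]:
    """f0 from the first normalized-autocorrelation peak, octave-corrected.

    The first local maximum of the (biased, zero-lag-normalized)
    autocorrelation in the lag band [fs/fmax, fs/fmin] gives a provisional
    f0.  A subglottal-resonance-boosted second harmonic puts that first peak
    at half the true period; in that case the peak near double the detected
    lag is *larger* than the detected one.  When a candidate peak at ~2x the
    lag has amplitude >= `subharmonic_threshold` times the first peak and
    exceeds it, f0 is recomputed from the longer lag.

    Returns ``(f0, autocorr_peak, subharmonic_peak)`` where
    ``subharmonic_peak`` is the largest secondary-peak amplitude between the
    zero lag and the period peak (NaN when none of at least
    `subharmonic_threshold` exists).

    Raises
    ------
    UnvoicedFrameError
        If no peak rises above `voicing_floor`.
    """
    x = np.asarray(window, dtype=float)
    x = x - np.mean(x)
    n = len(x)
    if n < 4 or not np.any(x):
        raise UnvoicedFrameError("degenerate window")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = rfft(x, nfft)
    r = irfft(spec * np.conj(spec), nfft)[:n]
    if r[0] <= 0:
        raise UnvoicedFrameError("zero-energy window")
    r = r / r[0]

    lmin = max(2, int(np.ceil(fs / fmax)))
    lmax = min(n - 2, int(np.floor(fs / fmin)))
    if lmax <= lmin:
        raise UnvoicedFrameError("window too short for the f0 search band")
    peaks = _local_maxima(r[: lmax + 2])
    peaks = peaks[(peaks >= lmin) & (peaks <= lmax)]
    peaks = peaks[r[peaks] > voicing_floor]
    if len(peaks) == 0:
        raise UnvoicedFrameError("no autocorrelation peak above the voicing floor")

    # ignore low sidelobes between harmonically related peaks: a candidate
    # "first peak" must reach half the strongest in-band peak
    gmax = float(np.max(r[peaks]))
    peaks = peaks[r[peaks] >= 0.5 * gmax]
    first = int(peaks[0])
    d1, a1 = _parabolic(r, first)
    lag = first + d1

    # octave-error correction: dominant peak near twice the detected lag
    cand_lo = int(np.floor(1.8 * lag))
    cand_hi = min(n - 2, int(np.ceil(2.2 * lag)))
    corrected = False
    if cand_hi > cand_lo:
        cpeaks = _local_maxima(r[: cand_hi + 2])
        cpeaks = cpeaks[(cpeaks >= cand_lo) & (cpeaks <= cand_hi)]
        if len(cpeaks):
            best = int(cpeaks[np.argmax(r[cpeaks])])
            d2, a2 = _parabolic(r, best)
            if a2 >= subharmonic_threshold * a1 and a2 > a1:
                lag, peak_amp = best + d2, a2
                corrected = True
    if not corrected:
        peak_amp = a1

    # secondary peak between zero lag and the period peak (VAD feature)
    sub_amp = math.nan
    inner = _local_maxima(r[: int(lag) + 1])
    inner = inner[(inner >= lmin) & (inner < int(lag))]
    if corrected:
        sub_amp = a1
    elif len(inner):
        amp = float(np.max(r[inner]))
        if amp >= subharmonic_threshold:
            sub_amp = amp

    return float(fs / lag), float(min(peak_amp, 1.0)), sub_amp


def cpp(window: np.ndarray, fs: float,
        fmin: float = 70.0, fmax: float = 500.0) -> float:
    """Cepstral peak prominence in dB.

    Hann-windowed, zero-padded FFT (next power of two >= 8192 at 20 kHz);
    real cepstrum of the dB-magnitude spectrum; prominence of the cepstral
    peak in the [1/fmax, 1/fmin] quefrency band above a linear regression
    line fitted to the cepstrum over that band.
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    w = get_window("hann", n, fftbins=True)
    nfft = max(8192, 1 << int(np.ceil(np.log2(max(n, 2)))))
    spec_db = 20.0 * np.log10(np.abs(np.fft.fft(x * w, nfft)) + 1e-300)
    ceps = np.real(np.fft.ifft(spec_db))
    ceps_db = 10.0 * np.log10(ceps**2 + 1e-300)

    q = np.arange(nfft) / fs  # quefrency in seconds
    i0 = int(np.ceil(fs / fmax))
    i1 = min(nfft // 2 - 1, int(np.floor(fs / fmin)))
    band = slice(i0, i1 + 1)
    coeffs = np.polyfit(q[band], ceps_db[band], 1)
    ipk = i0 + int(np.argmax(ceps_db[band]))
    baseline = float(np.polyval(coeffs, q[ipk]))
    return float(ceps_db[ipk] - baseline)


def lh_ratio(window: np.ndarray, fs: float, split_hz: float = 2000.0) -> float:
    """Low-to-high spectral power ratio (dB), split at 2000 Hz, Hann window."""
    x = np.asarray(window, dtype=float)
    w = get_window("hann", len(x), fftbins=True)
    p = np.abs(rfft(x * w)) ** 2
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    lo = float(np.sum(p[f <= split_hz]))
    hi = float(np.sum(p[f > split_hz]))
    return 10.0 * math.log10((lo + 1e-300) / (hi + 1e-300))


def fit_spl_mapping(acc_rms_db: np.ndarray, spl: np.ndarray) -> SplMapping:
    """Least-squares (dB, dB) line from paired calibration frames.

    Flags the mapping unreliable when fewer than 5 frames or less than a
    10-dB SPL span is available.
    """
    a = np.asarray(acc_rms_db, dtype=float)
    s = np.asarray(spl, dtype=float)
    if len(a) < 2 or len(a) != len(s):
        raise ValueError("need >= 2 paired frames")
    if np.ptp(a) == 0:
        raise DegenerateFitError("no variation in ACC level")
    slope, intercept = np.polyfit(a, s, 1)
    reliable = len(a) >= 5 and np.ptp(s) >= 10.0
    return SplMapping(float(slope), float(intercept), reliable)


def acc_to_spl(mapping: SplMapping, acc_rms: float | np.ndarray) -> float | np.ndarray:
    """Apply the log-log mapping to an ACC RMS value (linear cm/s^2 units)."""
    level = 20.0 * np.log10(np.asarray(acc_rms, dtype=float) / ACC_REF)
    out = mapping.slope * level + mapping.intercept
    return float(out) if np.isscalar(acc_rms) else out
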