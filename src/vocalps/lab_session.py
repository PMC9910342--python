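"""Segmentation of the laboratory calibration recording.

Splits the microphone channel into sustained-vowel segments, locates the
intraoral-pressure plateaus produced during the /p/ occlusions between
vowels, and derives the reference subglottal pressure for each vowel as the
mean of the peak plateau amplitudes immediately before and after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_signals import CalibratedSignal
from .errors import MissingReferenceError

#: default voiced-region energy threshold above the noise floor (dB)
DEFAULT_ENERGY_THRESHOLD_DB = 20.0
#: default minimum vowel duration (s)
DEFAULT_MIN_DURATION = 0.08
#: energy contour frame length (s)
ENERGY_FRAME_S = 0.010
#: minimum duration that guarantees a middle 50-ms analysis window
FEATURE_WINDOW_MIN_S = 0.060


@dataclass
class VowelSegment:
    """A vowel interval, half-open in samples: ``[start, end)``."""

    start: int
    end: int
    vowel: str | None = None            # "a" | "i" | "u"
    pitch_condition: str | None = None  # "comfortable" | "higher" | "lower"
    trial: int = 0
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration(self, fs: float) -> float:
        return self.n_samples / fs


@dataclass
class IopPlateau:
    peak_time: int          # sample index of the plateau peak
    peak_amplitude: float   # cm H2O, >= 0
    flatness: float = 0.0   # max-min over the top 20 ms, QC only

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")


@dataclass
class ReferencePs:
    segment: VowelSegment
    ps_ref: float           # cm H2O
    single_plateau: bool = False

    def __post_init__(self) -> None:
        if self.ps_ref < 0:
            raise ValueError("ps_ref must be >= 0")


def _energy_contour_db(x: np.ndarray, fs: float, frame_s: float) -> tuple[np.ndarray, int]:
    """Per-frame RMS in dB (frames non-overlapping, trailing partial dropped)."""
    flen = max(1, int(round(frame_s * fs)))
    n = len(x) // flen
    frames = x[: n * flen].reshape(n, flen)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    return 20.0 * np.log10(rms + 1e-12), flen


def segment_vowels(
    mic: CalibratedSignal,
    min_duration: float = DEFAULT_MIN_DURATION,
    energy_threshold_db: float = DEFAULT_ENERGY_THRESHOLD_DB,
) -> list[VowelSegment]:
    """Detect vowel segments from the microphone energy contour.

    A 10-ms RMS energy contour is thresholded at (noise floor +
    `energy_threshold_db`); runs of supra-threshold frames lasting at least
    `min_duration` become segments.  Segments shorter than 60 ms (no middle
    50-ms window) are kept but flagged ``short``.
    """
    if len(mic.samples) == 0:
        raise ValueError("empty microphone signal")
    contour, flen = _energy_contour_db(mic.samples, mic.fs, ENERGY_FRAME_S)
    if len(contour) == 0:
        return []
    noise_floor = np.percentile(contour, 10)
    above = contour > noise_floor + energy_threshold_db
    segments: list[VowelSegment] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            start, end = i * flen, j * flen
            if (end - start) / mic.fs >= min_duration:
                seg = VowelSegment(start=start, end=end)
                if (end - start) / mic.fs < FEATURE_WINDOW_MIN_S:
                    seg.qc_flags.append("short")
                segments.append(seg)
            i = j
        else:
            i += 1
    return segments


def detect_iop_plateaus(
    iop: CalibratedSignal,
    vowels: list[VowelSegment],
    min_peak_amplitude: float = 1.0,
) -> list[IopPlateau]:
    """One plateau per inter-vowel gap whose maximum exceeds the noise floor.

    The plateau peak is the maximum IOP amplitude within the gap (sample
    max; the paper does not state the estimator).  Gaps before the first and
    after the last vowel are included.  A flatness metric (max-min over the
    20 ms around the peak) is recorded for QC only.
    """
    from scipy.signal import find_peaks

    x = iop.samples
    bounds = [0] + [b for seg in vowels for b in (seg.start, seg.end)] + [len(x)]
    gaps = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    out: list[IopPlateau] = []
    half = max(1, int(round(0.010 * iop.fs)))
    min_sep = max(1, int(round(0.15 * iop.fs)))
    for g0, g1 in gaps:
        if g1 - g0 < 2:
            continue
        seg = x[g0:g1]
        if np.max(seg) < min_peak_amplitude:
            continue
        # a gap may hold several plateaus (e.g. trailing + leading between
        # breath strings); find all supra-threshold local maxima
        peaks, _ = find_peaks(seg, height=min_peak_amplitude,
                              distance=min_sep, plateau_size=(1, None))
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(seg))])
        for k in peaks:
            k = int(k)
            top = seg[max(0, k - half): k + half]
            out.append(IopPlateau(peak_time=g0 + k,
                                  peak_amplitude=float(seg[k]),
                                  flatness=float(np.ptp(top))))
    return out


def reference_ps(segment: VowelSegment, plateaus: list[IopPlateau]) -> ReferencePs:
    """Reference Ps = mean of the plateau peaks bracketing the segment.

    When only one adjacent plateau exists the result is flagged
    ``single_plateau`` (excluded from model fitting downstream); when none
    exists a :class:`MissingReferenceError` is raised.
    """
    preceding = [p for p in plateaus if p.peak_time <= segment.start]
    following = [p for p in plateaus if p.peak_time >= segment.end]
    prev = max(preceding, key=lambda p: p.peak_time) if preceding else None
    nxt = min(following, key=lambda p: p.peak_time) if following else None
    if prev is None and nxt is None:
        raise MissingReferenceError("no intraoral-pressure plateau adjacent to segment")
    if prev is not None and nxt is not None:
        return ReferencePs(segment, 0.5 * (prev.peak_amplitude + nxt.peak_amplitude))
    only = prev if prev is not None else nxt
    return ReferencePs(segment, only.peak_amplitude, single_plateau=True)


def reference_ps_table(
    vowels: list[VowelSegment],
    plateaus: list[IopPlateau],
    fs: float,
    session: str = "session",
) -> pd.DataFrame:
    """Tidy per-segment table (TSV-ready) of boundaries, labels and ps_ref."""
    rows = []
    for i, seg in enumerate(vowels):
        try:
            ref = reference_ps(seg, plateaus)
            ps, flags = ref.ps_ref, list(seg.qc_flags)
            if ref.single_plateau:
                flags.append("single_plateau")
        except MissingReferenceError:
            ps, flags = np.nan, list(seg.qc_flags) + ["no_reference"]
        rows.append({
            "session": session, "segment_id": i,
            "start_s": seg.start / fs, "end_s": seg.end / fs,
            "vowel": seg.vowel, "pitch_condition": seg.pitch_condition,
            "trial": seg.trial, "ps_ref_cmH2O": ps,
            "qc_flags": ";".join(flags),
        })
    return pd.DataFrame(rows)
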