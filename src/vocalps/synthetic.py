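"""Synthetic inputs with planted ground truth for every pipeline stage.

The human recordings behind this pipeline are not distributable, so every
consumer of lab or ambulatory data is exercised against generated signals:
glottal pulse trains with known OQ/SQ/amplitude, lab calibration sessions
(descending-loudness /p/-vowel strings with intraoral-pressure plateaus
bracketing each vowel, ACC forward-synthesized through a known skin/trachea
model, a planted linear ACC-RMS -> Ps law), and daylong voiced/unvoiced ACC
streams.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import ibif
from .ambulatory import frame_boundaries
from .core_signals import AMBULATORY_FS, LAB_FS, CalibratedSignal, Channel
from .acc_features import SplMapping, middle_window
from .ps_models import FEATURE_ORDER, KPA_TO_CMH2O, LineModel

#: two-formant resonators per vowel (F1, F2 in Hz) for the microphone channel
VOWEL_FORMANTS = {"a": (700.0, 1200.0), "i": (300.0, 2300.0), "u": (350.0, 800.0)}


# ---------------------------------------------------------------------------
# glottal pulse trains
# ---------------------------------------------------------------------------

def lf_pulse_train(
    f0: float,
    oq_target: float,
    sq_target: float,
    acfl_target: float,
    duration: float,
    fs: float,
    jitter_pct: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """LF-style glottal pulse train with known shape quotients.

    Each cycle has an open phase of ``oq_target`` % of the period, split
    into an opening ramp (sine quarter-wave, near-linear onset) and a
    closing fall (cosine quarter-wave, steepest at closure) whose durations
    are in the ratio ``sq_target``/100.  The closed phase is zero flow, so
    the peak-to-peak amplitude equals `acfl_target` exactly.  `jitter_pct`
    perturbs each cycle length (Gaussian, percent of the period).

    Returns ``(flow, truth)`` where `truth` records the planted values and
    per-cycle start samples.
    """
    if not 0 < oq_target < 100:
        raise ValueError("oq_target must be in (0, 100)")
    if sq_target <= 0:
        raise ValueError("sq_target must be > 0")
    rng = rng or np.random.default_rng(0)
    period = fs / f0
    n_total = int(round(duration * fs))
    out = np.zeros(n_total)
    starts = []
    pos = 0.0
    while True:
        if jitter_pct > 0:
            ti = period * (1.0 + (jitter_pct / 100.0) * rng.standard_normal())
        else:
            ti = float(round(period))   # integer period: identical cycles
        ti = max(4.0, ti)
        i0 = int(round(pos))
        i1 = int(round(pos + ti))
        if i1 >= n_total:
            break
        n = i1 - i0
        t = np.arange(n) / (i1 - i0)          # cycle phase in [0, 1)
        to = oq_target / 100.0
        t_op = to * sq_target / (100.0 + sq_target)
        t_cp = to - t_op
        cyc = np.zeros(n)
        rise = t < t_op
        cyc[rise] = np.sin(0.5 * math.pi * t[rise] / t_op)
        fall = (t >= t_op) & (t < to)
        cyc[fall] = np.cos(0.5 * math.pi * (t[fall] - t_op) / t_cp)
        out[i0:i1] = acfl_target * cyc
        starts.append(i0)
        pos += ti
    truth = {"f0": f0, "oq": oq_target, "sq": sq_target, "acfl": acfl_target,
             "cycle_starts": np.array(starts, dtype=int)}
    return out, truth


# ---------------------------------------------------------------------------
# participant specification
# ---------------------------------------------------------------------------

@dataclass
class ParticipantSpec:
    """Everything that defines one simulated participant."""

    sex: str = "female"
    #: planted Method-2 law: Ps[cm H2O] = ps_slope * ACCrms + ps_intercept
    ps_slope: float = 2.0
    ps_intercept: float = 3.0
    ibif_true: ibif.IbifParams = field(default_factory=lambda: ibif.DEFAULT_PARAMS)
    f0_by_pitch: dict = field(default_factory=lambda: {
        "comfortable": 190.0, "higher": 240.0, "lower": 150.0})
    oq: float = 55.0
    sq: float = 150.0
    vowels: tuple = ("a", "i", "u")
    pitches: tuple = ("comfortable", "higher", "lower")
    n_trials: int = 2
    syllables_per_trial: int = 6
    ps_range: tuple = (16.0, 4.0)     # descending loudness, cm H2O
    iop_noise_sigma: float = 0.0      # cm H2O on each plateau height
    acc_snr_db: float | None = None   # None -> noiseless ACC
    mic_noise_pa: float = 2e-4
    jitter_pct: float = 0.3
    quantize_16bit: bool = False
    seed: int = 0

    @property
    def fo_nominal(self) -> float:
        return 120.0 if self.sex == "male" else 190.0


def _resonator_sos(freqs: tuple, bw: float, fs: float):
    coeffs = []
    for f in freqs:
        r = math.exp(-math.pi * bw / fs)
        th = 2 * math.pi * f / fs
        coeffs.append(([1.0 - 2 * r * math.cos(th) + r * r],
                       [1.0, -2 * r * math.cos(th), r * r]))
    return coeffs


def _formant_filter(x: np.ndarray, vowel: str, fs: float) -> np.ndarray:
    y = x
    for b, a in _resonator_sos(VOWEL_FORMANTS[vowel], 90.0, fs):
        y = lfilter(b, a, y)
    return y


def _trapezoid(height: float, fs: float,
               rise=0.05, flat=0.08, fall=0.05) -> np.ndarray:
    nr, nf, nd = (int(round(d * fs)) for d in (rise, flat, fall))
    return height * np.concatenate([
        np.linspace(0, 1, nr, endpoint=False),
        np.ones(nf),
        np.linspace(1, 0, nd, endpoint=False),
    ])


@dataclass
class LabSession:
    mic: CalibratedSignal
    flow: CalibratedSignal
    iop: CalibratedSignal
    acc: CalibratedSignal
    truth: pd.DataFrame            # one row per planted vowel segment


def synthesize_lab_session(spec: ParticipantSpec) -> LabSession:
    """Simulated four-channel lab calibration session at 20 kHz.

    Each trial is a descending-loudness string: IOP plateau, vowel, plateau,
    vowel, ..., trailing plateau.  The true Ps of a vowel is the mean of its
    two bracketing (noise-free) plateau heights; the vowel's channels are
    scaled so the middle-50-ms ACC RMS equals (Ps - intercept)/slope of the
    planted law exactly.
    """
    fs = LAB_FS
    rng = np.random.default_rng(spec.seed)
    vowel_dur, plateau_pad, silence = 0.25, 0.04, 0.30
    plateau = _trapezoid(1.0, fs)
    n_plateau = len(plateau)
    n_vowel = int(round(vowel_dur * fs))
    n_sil = int(round(silence * fs))
    n_pad = int(round(plateau_pad * fs))

    per_syll = n_plateau + n_pad + n_vowel + n_pad
    per_trial = n_sil + spec.syllables_per_trial * per_syll + n_plateau + n_sil
    total = per_trial * spec.n_trials * len(spec.vowels) * len(spec.pitches)

    mic = np.zeros(total)
    flow = np.zeros(total)
    iop = np.zeros(total)
    acc = np.zeros(total)
    rows = []

    cursor = 0
    trial_id = 0
    for vowel in spec.vowels:
        for pitch in spec.pitches:
            f0 = spec.f0_by_pitch[pitch]
            for _ in range(spec.n_trials):
                cursor += n_sil
                n_syl = spec.syllables_per_trial
                heights = np.linspace(spec.ps_range[0], spec.ps_range[1], n_syl + 1)
                for k in range(n_syl):
                    # bracketing plateau (noise on height only)
                    h = heights[k] + (rng.normal(0, spec.iop_noise_sigma)
                                      if spec.iop_noise_sigma > 0 else 0.0)
                    iop[cursor:cursor + n_plateau] += max(h, 0) * (plateau / 1.0)
                    cursor += n_plateau + n_pad
                    # vowel
                    ps_true = 0.5 * (heights[k] + heights[k + 1])
                    target_rms = (ps_true - spec.ps_intercept) / spec.ps_slope
                    pulse, _ = lf_pulse_train(f0, spec.oq, spec.sq, 1.0,
                                              vowel_dur, fs, spec.jitter_pct, rng)
                    npad = int(round(0.05 * fs))
                    padded = np.concatenate([np.zeros(npad), pulse, np.zeros(npad)])
                    acc_raw = ibif.forward_filter(padded, spec.ibif_true, fs)[
                        npad:npad + n_vowel]
                    mid = middle_window(acc_raw, fs)
                    scale = target_rms / float(np.sqrt(np.mean(mid**2)))
                    acc[cursor:cursor + n_vowel] += scale * acc_raw
                    flow[cursor:cursor + n_vowel] += scale * pulse
                    # mic level tied to the ACC level (SPL = 60 + 20log10 RMS),
                    # so the log-log ACC->SPL mapping is exactly linear
                    dsrc = np.diff(scale * pulse, prepend=0.0)
                    mic_raw = _formant_filter(dsrc, vowel, fs)
                    mrms = float(np.sqrt(np.mean(middle_window(mic_raw, fs) ** 2)))
                    spl_target = 60.0 + 20.0 * math.log10(target_rms)
                    mic_v = mic_raw * (20e-6 * 10 ** (spl_target / 20.0) / mrms)
                    mic[cursor:cursor + n_vowel] += mic_v
                    rows.append({
                        "start": cursor, "end": cursor + n_vowel,
                        "vowel": vowel, "pitch_condition": pitch,
                        "trial": trial_id, "ps_true_cmH2O": ps_true,
                        "target_acc_rms": target_rms, "f0": f0,
                        "oq": spec.oq, "sq": spec.sq,
                    })
                    cursor += n_vowel + n_pad
                h = heights[n_syl] + (rng.normal(0, spec.iop_noise_sigma)
                                      if spec.iop_noise_sigma > 0 else 0.0)
                iop[cursor:cursor + n_plateau] += max(h, 0) * plateau
                cursor += n_plateau + n_sil
                trial_id += 1

    mic += rng.normal(0, spec.mic_noise_pa, total)
    if spec.iop_noise_sigma > 0:
        iop += rng.normal(0, spec.iop_noise_sigma / 10.0, total)
    if spec.acc_snr_db is not None:
        sig_rms = float(np.sqrt(np.mean(acc[acc != 0] ** 2))) if np.any(acc) else 1.0
        acc += rng.normal(0, sig_rms * 10 ** (-spec.acc_snr_db / 20.0), total)
    if spec.quantize_16bit:
        for arr in (mic, flow, iop, acc):
            peak = np.max(np.abs(arr)) or 1.0
            np.round(arr / peak * 32767, out=arr)
            arr *= peak / 32767

    return LabSession(
        mic=CalibratedSignal(mic, fs, Channel.MIC),
        flow=CalibratedSignal(flow, fs, Channel.FLOW),
        iop=CalibratedSignal(iop, fs, Channel.IOP),
        acc=CalibratedSignal(acc, fs, Channel.ACC),
        truth=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# daylong ambulatory stream
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDay:
    acc: CalibratedSignal
    truth: pd.DataFrame            # one row per 50-ms frame
    spl_mapping: SplMapping
    ps_model: LineModel            # the planted law as a deployable model
    ibif_params: ibif.IbifParams


def synthesize_day(
    spec: ParticipantSpec,
    duration_h: float,
    voiced_fraction: float = 0.3,
    seed: int | None = None,
    acc_snr_db: float = 28.0,
    spl_intercept: float = 60.0,
) -> SyntheticDay:
    """Daylong ACC stream at 11,025 Hz with frame-aligned voiced spans.

    Voiced and unvoiced span lengths are drawn randomly but quantized to the
    50-ms frame grid, so no frame straddles a boundary.  Loudness and pitch
    drift slowly (sinusoid + random walk).  Per-frame true Ps follows the
    planted law applied to the frame's ACC RMS; the returned
    :class:`LineModel` is that same law, deployable by ``process_day``.
    """
    if not 0 <= voiced_fraction <= 1:
        raise ValueError("voiced_fraction must be within [0, 1]")
    fs = AMBULATORY_FS
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_samples = int(round(duration_h * 3600.0 * fs))
    edges = frame_boundaries(n_samples, fs)
    n_frames = len(edges) - 1
    acc = np.zeros(n_samples)
    voiced_flags = np.zeros(n_frames, dtype=bool)
    f0_truth = np.full(n_frames, np.nan)

    f0_base = spec.f0_by_pitch["comfortable"]
    mean_voiced_frames = 30          # 1.5 s
    i = 0
    t_phase = rng.uniform(0, 2 * math.pi)
    walk = 0.0
    while i < n_frames:
        v_len = max(8, int(rng.normal(mean_voiced_frames, 8)))
        if voiced_fraction >= 1.0:
            u_len = 0
        elif voiced_fraction <= 0.0:
            v_len, u_len = 0, n_frames - i
        else:
            u_len = max(1, int(round(v_len * (1 - voiced_fraction) / voiced_fraction
                                     * rng.uniform(0.7, 1.3))))
        v_len = min(v_len, n_frames - i)
        if v_len > 0:
            s0, s1 = edges[i], edges[i + v_len]
            t_mid = (i + v_len / 2) * 0.05
            walk = 0.95 * walk + rng.normal(0, 0.8)
            level_db = 6.0 * math.sin(2 * math.pi * t_mid / 600.0 + t_phase) + walk
            level_db = float(np.clip(level_db, -8, 8))
            f0 = float(np.clip(f0_base * (1 + 0.15 * math.sin(
                2 * math.pi * t_mid / 420.0 + t_phase) + rng.normal(0, 0.03)),
                70 * 1.3, 450.0))
            pulse, _ = lf_pulse_train(f0, spec.oq, spec.sq, 1.0,
                                      (s1 - s0) / fs + 0.01, fs, 0.3, rng)
            pulse = pulse[: s1 - s0]
            npad = int(round(0.03 * fs))
            padded = np.concatenate([np.zeros(npad), pulse, np.zeros(npad)])
            span = ibif.forward_filter(padded, spec.ibif_true, fs)[npad:npad + (s1 - s0)]
            span_rms = float(np.sqrt(np.mean(span**2))) or 1.0
            target_rms = 3.0 * 10 ** (level_db / 20.0)
            span *= target_rms / span_rms
            # fade edges within the boundary frames to avoid clicks
            nramp = min(64, len(span) // 4)
            ramp = np.linspace(0, 1, nramp)
            span[:nramp] *= ramp
            span[-nramp:] *= ramp[::-1]
            span += rng.normal(0, target_rms * 10 ** (-acc_snr_db / 20.0), len(span))
            acc[s0:s1] = span
            voiced_flags[i:i + v_len] = True
            f0_truth[i:i + v_len] = f0
            i += v_len
        if u_len > 0:
            u_len = min(u_len, n_frames - i)
            s0, s1 = edges[i], edges[min(i + u_len, n_frames)]
            acc[s0:s1] = rng.normal(0, 0.02, s1 - s0)
            i += u_len
        if v_len == 0 and u_len == 0:
            break

    mapping = SplMapping(slope=1.0, intercept=spl_intercept)
    frame_rms = np.array([
        float(np.sqrt(np.mean(acc[edges[j]: edges[j + 1]] ** 2)))
        for j in range(n_frames)])
    ps_true = np.where(voiced_flags,
                       spec.ps_slope * frame_rms + spec.ps_intercept, np.nan)
    truth = pd.DataFrame({
        "frame": np.arange(n_frames),
        "t_start_s": np.arange(n_frames) * 0.05,
        "voiced": voiced_flags,
        "f0_true": f0_truth,
        "acc_rms": frame_rms,
        "ps_true_cmH2O": ps_true,
    })
    return SyntheticDay(
        acc=CalibratedSignal(acc, fs, Channel.ACC),
        truth=truth,
        spl_mapping=mapping,
        ps_model=LineModel(spec.ps_slope, spec.ps_intercept, n_points=0),
        ibif_params=spec.ibif_true,
    )


# ---------------------------------------------------------------------------
# feature-level cohorts (for model-comparison experiments)
# ---------------------------------------------------------------------------

def synthesize_feature_cohort(
    n_participants: int,
    n_segments: int = 60,
    seed: int = 0,
    oq_coeff: float = 0.15,
    noise_sd: float = 0.5,
    spl_noise_db: float = 2.0,
) -> list[dict]:
    """Per-participant feature tables with a planted Ps law.

    The law is Ps = a*RMS + c*(OQ - 55) + b + noise with participant-specific
    a, b; SPL is tied to the true Ps by inverting the Method-1 formula plus
    `spl_noise_db` of noise, so Method 1 tracks Ps only loosely.  The other
    eight measures are independent decoys.  Each entry carries ``features``
    (DataFrame with the ten measures + SPL), ``ps_ref`` and ``fo_nominal``.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_participants):
        sex = rng.choice(["male", "female"])
        fo_n = 120.0 if sex == "male" else 190.0
        a = rng.uniform(1.5, 2.5)
        b = rng.uniform(2.0, 4.0)
        rms = rng.uniform(1.0, 8.0, n_segments)
        oq = rng.uniform(40.0, 70.0, n_segments)
        f0 = rng.normal(fo_n, 15.0, n_segments)
        ps = a * rms + oq_coeff * (oq - 55.0) + b \
            + rng.normal(0, noise_sd, n_segments)
        ps_kpa = np.maximum(ps, 0.5) / KPA_TO_CMH2O
        resid = np.maximum(ps_kpa - 0.14 - 0.06 * (f0 / fo_n) ** 2, 1e-3)
        spl = 88.5 + 27.3 * np.log10(resid) + rng.normal(0, spl_noise_db, n_segments)
        features = pd.DataFrame({
            "RMS": rms, "F0": f0,
            "CPP": rng.normal(15, 3, n_segments),
            "ACFL": rng.uniform(100, 400, n_segments),
            "MFDR": rng.uniform(100, 500, n_segments),
            "OQ": oq,
            "SQ": rng.uniform(110, 250, n_segments),
            "H1H2": rng.normal(8, 3, n_segments),
            "HRF": rng.normal(-8, 3, n_segments),
            "NAQ": rng.uniform(0.1, 0.3, n_segments),
            "SPL": spl,
        })
        cohort.append({"features": features, "ps_ref": ps, "fo_nominal": fo_n,
                       "sex": sex, "law": (a, oq_coeff, b)})
    return cohort


__all__ = [
    "lf_pulse_train", "ParticipantSpec", "LabSession", "synthesize_lab_session",
    "SyntheticDay", "synthesize_day", "synthesize_feature_cohort",
    "VOWEL_FORMANTS", "FEATURE_ORDER",
]
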