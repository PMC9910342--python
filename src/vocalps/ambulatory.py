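"""Daylong ACC processing: framing, voice-activity detection, Ps tracking.

The daylong stream is cut into nonoverlapping 50-ms frames.  Five features
(ACC-mapped SPL, f0, autocorrelation peak, subharmonic peak, low/high
spectral ratio) gate each frame through the voice-activity detector; voiced
frames are inverse-filtered with the participant's fixed IBIF model, the ten
vocal-function measures are computed, physiologically implausible frames are
screened out, and Ps is predicted on the survivors.  Summaries mirror the
daylong statistics tables (trimmed percentiles, histogram mode for Ps,
phonation time) plus 5-min rolling profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acc_features as af
from . import ibif
from .core_signals import CalibratedSignal
from .errors import ConfigurationError, UnvoicedFrameError
from .ps_models import LineModel, StepwiseModel, predict_ps

FRAME_S = 0.050


@dataclass(frozen=True)
class VadCriteria:
    """Inclusive voicing ranges for the five VAD features (published defaults)."""

    spl: tuple[float, float] = (45.0, 130.0)
    f0: tuple[float, float] = (70.0, 1000.0)
    autocorr_peak: tuple[float, float] = (0.60, 1.0)
    subharmonic_peak: tuple[float, float] = (0.25, 1.0)
    lh_ratio: tuple[float, float] = (22.0, 50.0)

    def __post_init__(self) -> None:
        for name in ("spl", "f0", "autocorr_peak", "subharmonic_peak", "lh_ratio"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")


@dataclass
class FrameRecord:
    t_start: float
    voiced: bool
    features: af.FrameFeatures | None = None
    glottal: ibif.GlottalFeatures | None = None
    valid: bool = False
    reasons: list[str] = field(default_factory=list)
    ps_est: float | None = None


def frame_boundaries(n_samples: int, fs: float, frame_s: float = FRAME_S) -> np.ndarray:
    """Sample indices of nonoverlapping frame edges on the exact time grid.

    Frame i covers ``[round(i*frame_s*fs), round((i+1)*frame_s*fs))``; at
    11,025 Hz this alternates 551/552-sample frames so that the frame count
    equals floor(duration / frame_s) with no drift.  The trailing partial
    frame is dropped.
    """
    n_frames = int(math.floor(n_samples / fs / frame_s + 1e-9))
    return np.round(np.arange(n_frames + 1) * frame_s * fs).astype(int)


def frame_stream(acc: CalibratedSignal, frame_s: float = FRAME_S) -> list[np.ndarray]:
    """Nonoverlapping 50-ms frames; the trailing partial frame is dropped."""
    edges = frame_boundaries(len(acc.samples), acc.fs, frame_s)
    return [acc.samples[edges[i]: edges[i + 1]] for i in range(len(edges) - 1)]


def _in(v: float, rng: tuple[float, float]) -> bool:
    return rng[0] <= v <= rng[1]


def is_voiced(features: af.FrameFeatures, c: VadCriteria | None = None) -> bool:
    """Conjunction of the five inclusive range tests.

    A NaN subharmonic peak means no secondary peak exists; the criterion
    applies only "if it exists", so NaN passes.  A NaN f0 (aperiodic frame)
    fails.
    """
    c = c or VadCriteria()
    if math.isnan(features.f0) or math.isnan(features.autocorr_peak):
        return False
    ok = (_in(features.spl, c.spl)
          and _in(features.f0, c.f0)
          and _in(features.autocorr_peak, c.autocorr_peak)
          and _in(features.lh_ratio, c.lh_ratio))
    if not math.isnan(features.subharmonic_peak):
        ok = ok and _in(features.subharmonic_peak, c.subharmonic_peak)
    return ok


def compute_frame_features(
    frame: np.ndarray,
    fs: float,
    spl_mapping: af.SplMapping,
    with_cpp: bool = True,
) -> af.FrameFeatures:
    rms = af.frame_rms(frame)
    spl = af.acc_to_spl(spl_mapping, rms) if rms > 0 else -math.inf
    try:
        f0, acp, sub = af.f0_autocorrelation(frame, fs)
    except UnvoicedFrameError:
        f0, acp, sub = math.nan, math.nan, math.nan
    return af.FrameFeatures(
        rms=rms, f0=f0,
        cpp=af.cpp(frame, fs) if with_cpp else math.nan,
        spl=spl, autocorr_peak=acp, subharmonic_peak=sub,
        lh_ratio=af.lh_ratio(frame, fs),
    )


def process_day(
    acc: CalibratedSignal,
    spl_mapping: af.SplMapping,
    ibif_params: ibif.IbifParams,
    ps_model: LineModel | StepwiseModel,
    criteria: VadCriteria | None = None,
) -> list[FrameRecord]:
    """Run the full per-frame chain over a daylong calibrated ACC stream."""
    if spl_mapping is None or ibif_params is None or ps_model is None:
        raise ConfigurationError("spl_mapping, ibif_params and ps_model are required")
    criteria = criteria or VadCriteria()
    frames = frame_stream(acc)
    fs = acc.fs
    edges = frame_boundaries(len(acc.samples), acc.fs)
    ctx = int(round(0.010 * fs))   # inverse-filter context to limit edge ringing
    records: list[FrameRecord] = []
    for i, frame in enumerate(frames):
        t0 = i * FRAME_S
        feats = compute_frame_features(frame, fs, spl_mapping, with_cpp=False)
        if not is_voiced(feats, criteria):
            records.append(FrameRecord(t_start=t0, voiced=False, features=feats))
            continue
        feats.cpp = af.cpp(frame, fs)
        glottal = None
        lo = max(0, edges[i] - ctx)
        hi = min(len(acc.samples), edges[i + 1] + ctx)
        padded = acc.samples[lo:hi]
        try:
            g = ibif.inverse_filter(padded, ibif_params, fs, f0=feats.f0)
            g.flow = g.flow[edges[i] - lo: len(g.flow) - (hi - edges[i + 1])]
            g.f0 = feats.f0
            glottal = ibif.time_domain_features(g)
            glottal.h1h2, glottal.hrf = ibif.spectral_features(g)
            keep, reasons = ibif.validity_filter(glottal, feats.f0)
        except (ibif.InsufficientDataError, ibif.UndefinedFeaturesError) as exc:
            keep, reasons = False, [type(exc).__name__]
        rec = FrameRecord(t_start=t0, voiced=True, features=feats,
                          glottal=glottal, valid=keep, reasons=reasons)
        if keep:
            row = {
                "RMS": feats.rms, "F0": feats.f0, "CPP": feats.cpp,
                "ACFL": glottal.acfl, "MFDR": glottal.mfdr, "OQ": glottal.oq,
                "SQ": glottal.sq, "H1H2": glottal.h1h2, "HRF": glottal.hrf,
                "NAQ": glottal.naq,
            }
            if isinstance(ps_model, LineModel):
                rec.ps_est = float(np.asarray(predict_ps(ps_model, [feats.rms]))[0])
            else:
                rec.ps_est = float(predict_ps(ps_model, row)[0])
        records.append(rec)
    return records


def records_to_frame(records: list[FrameRecord]) -> pd.DataFrame:
    """Flatten frame records to a tidy table (TSV-ready)."""
    rows = []
    for r in records:
        row = {"t_start_s": r.t_start, "voiced": r.voiced, "valid": r.valid,
               "reasons": ";".join(r.reasons),
               "ps_est_cmH2O": r.ps_est if r.ps_est is not None else np.nan}
        if r.features is not None:
            row.update(rms_cms2=r.features.rms, f0_hz=r.features.f0,
                       cpp_db=r.features.cpp, spl_db15cm=r.features.spl,
                       autocorr_peak=r.features.autocorr_peak,
                       lh_ratio_db=r.features.lh_ratio)
        if r.glottal is not None:
            row.update(acfl_mls=r.glottal.acfl, mfdr_ls2=r.glottal.mfdr,
                       oq_pct=r.glottal.oq, sq_pct=r.glottal.sq,
                       h1h2_db=r.glottal.h1h2, hrf_db=r.glottal.hrf,
                       naq=r.glottal.naq)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# daylong summaries
# ---------------------------------------------------------------------------

PS_MODE_BIN = 0.5
PS_MODE_RANGE = (0.0, 40.0)


def _moments(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    return {"mean": mean, "sd": sd, "skewness": skew,
            "p5": float(np.percentile(x, 5)),
            "p95": float(np.percentile(x, 95))}


def ps_mode(ps: np.ndarray,
            bin_width: float = PS_MODE_BIN,
            rng: tuple[float, float] = PS_MODE_RANGE) -> float:
    """Histogram mode: center of the maximal 0.5-cm-H2O bin (ties -> lower)."""
    edges = np.arange(rng[0], rng[1] + bin_width, bin_width)
    counts, _ = np.histogram(ps, bins=edges)
    i = int(np.argmax(counts))
    return float(edges[i] + bin_width / 2)


@dataclass
class DaySummary:
    monitoring_duration_h: float
    phonation_time_s: float
    phonation_pct: float
    n_frames: int
    n_voiced: int
    n_valid: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    ps_mode: float | None = None


def summarize_day(records: list[FrameRecord]) -> DaySummary:
    """Daylong univariate statistics over voiced, validity-screened frames."""
    n = len(records)
    voiced = [r for r in records if r.voiced]
    valid = [r for r in voiced if r.valid and r.ps_est is not None]
    summary = DaySummary(
        monitoring_duration_h=n * FRAME_S / 3600.0,
        phonation_time_s=len(voiced) * FRAME_S,
        phonation_pct=100.0 * len(voiced) / n if n else 0.0,
        n_frames=n, n_voiced=len(voiced), n_valid=len(valid),
    )
    if not valid:
        return summary
    ps = np.array([r.ps_est for r in valid])
    summary.stats["ps"] = _moments(ps)
    summary.ps_mode = ps_mode(ps)
    for name, getter in [
        ("spl", lambda r: r.features.spl),
        ("f0", lambda r: r.features.f0),
        ("cpp", lambda r: r.features.cpp),
        ("h1h2", lambda r: r.glottal.h1h2 if r.glottal else math.nan),
    ]:
        raw = []
        for r in valid:
            try:
                raw.append(getter(r))
            except AttributeError:   # records rebuilt from a bare frame table
                raw.append(math.nan)
        vals = np.array(raw, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            summary.stats[name] = _moments(vals)
    return summary


def rolling_profile(
    records: list[FrameRecord],
    window_s: float = 300.0,
    step_s: float = 30.0,
) -> pd.DataFrame:
    """Percent phonation and Ps median/p95 over sliding windows.

    One row per step from t=0; windows extending past the stream end are
    produced but flagged ``full_window=False``.
    """
    if not records:
        return pd.DataFrame()
    t = np.array([r.t_start for r in records])
    voiced = np.array([r.voiced for r in records])
    ps = np.array([r.ps_est if r.ps_est is not None else np.nan for r in records])
    duration = t[-1] + FRAME_S
    rows = []
    start = 0.0
    while start < duration:
        end = start + window_s
        sel = (t >= start) & (t < end)
        n = int(np.sum(sel))
        pvals = ps[sel]
        pvals = pvals[np.isfinite(pvals)]
        rows.append({
            "t_start_s": start,
            "full_window": end <= duration + 1e-9,
            "pct_phonation": 100.0 * float(np.mean(voiced[sel])) if n else np.nan,
            "ps_median": float(np.median(pvals)) if len(pvals) else np.nan,
            "ps_p95": float(np.percentile(pvals, 95)) if len(pvals) else np.nan,
        })
        start += step_s
    return pd.DataFrame(rows)


def select_ambulatory_ibif(segment_table: pd.DataFrame) -> int:
    """Index of the lab segment supplying the time-invariant day IBIF model.

    The /a/-vowel, comfortable-pitch segment with the highest reference Ps.
    `segment_table` needs columns ``vowel``, ``pitch_condition``,
    ``ps_ref_cmH2O``.
    """
    cand = segment_table[
        (segment_table["vowel"] == "a")
        & (segment_table["pitch_condition"] == "comfortable")
        & segment_table["ps_ref_cmH2O"].notna()
    ]
    if cand.empty:
        raise ConfigurationError("no /a/ comfortable-pitch segment with reference Ps")
    return int(cand["ps_ref_cmH2O"].idxmax())
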