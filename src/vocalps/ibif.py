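"""Subglottal impedance-based inverse filtering (IBIF) of the ACC signal.

The forward model maps glottal airflow (mL/s, injected at the glottal end of
the trachea) to neck-surface acceleration (cm/s^2) as the cascade of

* a uniform lossy transmission line of length ``tracheal_length`` (cm) with
  a resistive lung termination, evaluated at ``acc_position`` cm below the
  glottis (this produces the familiar quarter-wave subglottal resonances);
* a one-degree-of-freedom per-area mass-spring-damper neck-skin model
  (``skin_inertance`` kg/m^2, ``skin_resistance`` N*s/m^3, ``skin_stiffness``
  N/m^3) converting tracheal wall pressure to surface acceleration.

This realization is the minimal structure consistent with the five named
parameters; it is an approximation of the published subglottal impedance
model, not a coefficient-level reproduction.  Inversion divides the ACC
spectrum by the regularized transfer function (magnitude floored at -60 dB
of its peak) and band-limits the result to 50-4000 Hz.

The module also fits the five parameters by particle swarm optimization
against a simultaneously recorded oral-airflow reference, and computes the
time-domain and spectral glottal-airflow measures (ACFL, MFDR, OQ, SQ,
H1-H2, HRF, NAQ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal import find_peaks

from .errors import (
    InsufficientDataError,
    InvalidParamsError,
    UndefinedFeaturesError,
)

# -- physical constants (subglottal air column) ------------------------------
AIR_DENSITY = 1.14          # kg/m^3 at body temperature
SOUND_SPEED = 350.0         # m/s in the subglottal airways
TRACHEA_AREA = 2.5e-4       # m^2
#: propagation loss: alpha(f) = LOSS_A0 + LOSS_A1*sqrt(f)  [1/m]
LOSS_A0 = 0.05
LOSS_A1 = 0.012
#: lung termination impedance as a fraction of the characteristic impedance
LUNG_Z_RATIO = 1.0 / 3.0
#: fraction of the tracheal plane-wave pressure reaching the skin surface
#: (tissue attenuation between the tracheal wall and the neck surface);
#: brings the composite gain to the observed cm/s^2-per-mL/s scale
WALL_COUPLING = 3e-4

#: inverse-filter band (Hz)
BAND_LO = 50.0
BAND_HI = 4000.0
#: spectral-division floor relative to the peak transfer magnitude
REG_FLOOR_DB = -60.0

ML_PER_M3 = 1e6             # mL per m^3
CM_PER_M = 100.0
#: 1 L/s^2 expressed in mL/s^2 (MFDR is reported in L/s^2)
MLS2_PER_LS2 = 1000.0

#: fraction of cycle peak-to-peak used as the open-phase threshold
OPEN_PHASE_THRESHOLD = 0.10


@dataclass(frozen=True)
class IbifParams:
    """Five-parameter skin/trachea model; all strictly positive."""

    skin_inertance: float     # kg/m^2
    skin_resistance: float    # N*s/m^3
    skin_stiffness: float     # N/m^3
    tracheal_length: float    # cm
    acc_position: float       # cm below the glottis

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not (v > 0 and math.isfinite(v)):
                raise InvalidParamsError(f"{name} must be finite and > 0, got {v}")
        if self.acc_position >= self.tracheal_length:
            raise InvalidParamsError("acc_position must be < tracheal_length")

    def as_array(self) -> np.ndarray:
        return np.array([self.skin_inertance, self.skin_resistance,
                         self.skin_stiffness, self.tracheal_length,
                         self.acc_position])

    @classmethod
    def from_array(cls, a) -> "IbifParams":
        return cls(*(float(v) for v in a))


#: physiological default search bounds for the PSO fit
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "skin_inertance": (0.5, 4.0),
    "skin_resistance": (200.0, 4000.0),
    "skin_stiffness": (2e5, 4e6),
    "tracheal_length": (8.0, 16.0),
    "acc_position": (2.0, 7.9),
}

DEFAULT_PARAMS = IbifParams(
    skin_inertance=1.5,
    skin_resistance=400.0,
    skin_stiffness=1.3e6,
    tracheal_length=12.0,
    acc_position=5.0,
)


@dataclass
class GlottalWaveform:
    """Zero-mean estimated glottal airflow (mL/s)."""

    flow: np.ndarray
    fs: float
    f0: float

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)


@dataclass
class GlottalFeatures:
    acfl: float = math.nan    # mL/s, peak-to-peak flow amplitude
    mfdr: float = math.nan    # L/s^2, magnitude of the steepest flow decline
    oq: float = math.nan      # %, open time / cycle period
    sq: float = math.nan      # %, 100 * opening time / closing time
    naq: float = math.nan     # unitless, (ACFL/MFDR)/period
    h1h2: float = math.nan    # dB
    hrf: float = math.nan     # dB
    f0: float = math.nan      # Hz
    t_open: float = math.nan  # s, mean open-phase duration
    t_closed: float = math.nan
    flags: list[str] = field(default_factory=list)


def ibif_transfer(params: IbifParams, fs: float, n_freq: int) -> np.ndarray:
    """Complex glottal-flow -> ACC-acceleration response on the rfft grid.

    `n_freq` is the FFT length; the returned array has ``n_freq//2 + 1``
    bins.  Input flow is in mL/s, output acceleration in cm/s^2.
    """
    f = rfftfreq(n_freq, 1.0 / fs)
    w = 2.0 * math.pi * f

    zc = AIR_DENSITY * SOUND_SPEED / TRACHEA_AREA
    zl = LUNG_Z_RATIO * zc
    gamma = (LOSS_A0 + LOSS_A1 * np.sqrt(f)) + 1j * w / SOUND_SPEED
    refl = (zl - zc) / (zl + zc)
    L = params.tracheal_length / CM_PER_M
    x = params.acc_position / CM_PER_M
    # flow source at the glottis end, termination at the lungs:
    # P(x) = Zc * U * (e^{-gx} + G e^{-g(2L-x)}) / (1 - G e^{-2gL})
    num = np.exp(-gamma * x) + refl * np.exp(-gamma * (2 * L - x))
    den = 1.0 - refl * np.exp(-2.0 * gamma * L)
    h_trachea = zc * num / den                         # Pa per (m^3/s)

    m, r, k = params.skin_inertance, params.skin_resistance, params.skin_stiffness
    h_skin = -(w**2) / (k - m * w**2 + 1j * w * r)     # (m/s^2) per Pa

    return h_trachea * h_skin * WALL_COUPLING * (CM_PER_M / ML_PER_M3)


def _band_mask(f: np.ndarray, lo: float = BAND_LO, hi: float = BAND_HI,
               taper_lo: float = 10.0, taper_hi: float = 400.0) -> np.ndarray:
    """Raised-cosine band-pass weights on a frequency grid."""
    w = np.zeros_like(f)
    w[(f >= lo) & (f <= hi)] = 1.0
    rise = (f > lo - taper_lo) & (f < lo)
    w[rise] = 0.5 * (1 + np.cos(math.pi * (lo - f[rise]) / taper_lo))
    fall = (f > hi) & (f < hi + taper_hi)
    w[fall] = 0.5 * (1 + np.cos(math.pi * (f[fall] - hi) / taper_hi))
    return w


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase spectral band-pass with raised-cosine edges."""
    n = len(x)
    spec = rfft(x)
    spec *= _band_mask(rfftfreq(n, 1.0 / fs), lo, hi)
    return irfft(spec, n)


def forward_filter(flow: np.ndarray, params: IbifParams, fs: float) -> np.ndarray:
    """Synthesize an ACC signal (cm/s^2) from glottal airflow (mL/s)."""
    n = len(flow)
    h = ibif_transfer(params, fs, n)
    return irfft(rfft(flow) * h, n)


def inverse_filter(
    acc: np.ndarray,
    params: IbifParams,
    fs: float,
    f0: float | None = None,
) -> GlottalWaveform:
    """Estimate zero-mean glottal airflow from a calibrated ACC segment.

    The transfer magnitude is floored at -60 dB of its in-band peak before
    division, and the result is band-limited to 50-4000 Hz.
    """
    acc = np.asarray(acc, dtype=float)
    n = len(acc)
    if f0 is not None and n < 3 * fs / f0:
        raise InsufficientDataError("segment shorter than 3 pitch periods")
    if n < 8:
        raise InsufficientDataError("segment too short to invert")
    h = ibif_transfer(params, fs, n)
    mag = np.abs(h)
    floor = np.max(mag) * 10.0 ** (REG_FLOOR_DB / 20.0)
    low = mag < floor
    h_reg = h.copy()
    # keep phase, raise magnitude to the floor (DC bin has zero magnitude)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = h[low] * (floor / mag[low])
    scaled[~np.isfinite(scaled)] = floor
    h_reg[low] = scaled
    flow = rfft(acc) / h_reg
    flow *= _band_mask(rfftfreq(n, 1.0 / fs))
    out = irfft(flow, n)
    out = out - np.mean(out)
    return GlottalWaveform(flow=out, fs=fs, f0=f0 if f0 else math.nan)


# ---------------------------------------------------------------------------
# PSO parameter fitting
# ---------------------------------------------------------------------------

def _make_objective(
    acc: np.ndarray,
    flow_ref: np.ndarray,
    fs: float,
    bounds: dict[str, tuple[float, float]],
):
    """Closure computing the waveform-matching PSO objective.

    Normalized MSE between the inverse-filtered ACC and the mean-subtracted,
    50-1100 Hz band-passed oral-airflow reference, after aligning the two by
    the integer lag (within +/-10 ms) maximizing their cross-correlation.
    The reference path is precomputed once.
    """
    lo = np.array([bounds[k][0] for k in DEFAULT_BOUNDS])
    hi = np.array([bounds[k][1] for k in DEFAULT_BOUNDS])
    acc = np.asarray(acc, dtype=float)
    ref = np.asarray(flow_ref, dtype=float)
    ref = bandpass(ref - np.mean(ref), fs, 50.0, 1100.0)
    denom = float(np.mean(ref**2)) + 1e-30
    max_lag = int(round(0.010 * fs))

    def objective(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        if xc[4] >= xc[3]:
            xc = xc.copy()
            xc[4] = 0.99 * xc[3]
        params = IbifParams.from_array(xc)
        est = inverse_filter(acc, params, fs).flow
        est_b = bandpass(est, fs, 50.0, 1100.0)
        from scipy.signal import correlate, correlation_lags
        c = correlate(est_b, ref, mode="full", method="fft")
        lags = correlation_lags(len(est_b), len(ref), mode="full")
        keep = np.abs(lags) <= max_lag
        lag = int(lags[keep][np.argmax(c[keep])])
        if lag >= 0:
            a, b = est_b[lag:], ref[: len(ref) - lag]
        else:
            a, b = est_b[: len(est_b) + lag], ref[-lag:]
        m = min(len(a), len(b))
        return float(np.mean((a[:m] - b[:m]) ** 2) / denom)

    return objective


def ibif_objective(
    x: np.ndarray,
    acc: np.ndarray,
    flow_ref: np.ndarray,
    fs: float,
    bounds: dict[str, tuple[float, float]],
) -> float:
    """One-shot evaluation of the PSO objective (see :func:`_make_objective`)."""
    return _make_objective(acc, flow_ref, fs, bounds)(np.asarray(x, dtype=float))


def fit_ibif_pso(
    acc: np.ndarray,
    flow_ref: np.ndarray,
    fs: float,
    bounds: dict[str, tuple[float, float]] | None = None,
    swarm_size: int = 30,
    n_iter: int = 200,
    seed: int = 0,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
    polish: bool = True,
) -> tuple[IbifParams, float]:
    """Fit the five IBIF parameters by seeded particle swarm optimization.

    A deterministic Nelder-Mead polish of the swarm's best particle (clipped
    to the bounds) refines the final answer.  Returns ``(params, objective)``.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    lo = np.array([bounds[k][0] for k in DEFAULT_BOUNDS])
    hi = np.array([bounds[k][1] for k in DEFAULT_BOUNDS])
    rng = np.random.default_rng(seed)
    d = len(lo)
    fobj = _make_objective(acc, flow_ref, fs, bounds)

    pos = lo + (hi - lo) * rng.random((swarm_size, d))
    vel = 0.1 * (hi - lo) * (rng.random((swarm_size, d)) - 0.5)
    pbest = pos.copy()
    pbest_val = np.array([fobj(p) for p in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    vmax = 0.5 * (hi - lo)
    for _ in range(n_iter):
        r1 = rng.random((swarm_size, d))
        r2 = rng.random((swarm_size, d))
        vel = (inertia * vel
               + cognitive * r1 * (pbest - pos)
               + social * r2 * (gbest - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([fobj(p) for p in pos])
        better = vals < pbest_val
        pbest[better] = pos[better]
        pbest_val[better] = vals[better]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    if polish:
        # The objective is multimodal in the (tracheal_length, acc_position)
        # plane once the skin parameters co-vary; rescan that plane with the
        # swarm-best skin parameters, then polish the best starts with
        # Nelder-Mead in bound-normalized coordinates.
        span = hi - lo

        def fnorm(u: np.ndarray) -> float:
            return fobj(lo + np.clip(u, 0.0, 1.0) * span)

        starts = [gbest]
        Ls = np.linspace(lo[3], hi[3], 9)
        xs = np.linspace(lo[4], hi[4], 9)
        grid = []
        for L in Ls:
            for xp in xs:
                if xp >= L:
                    continue
                cand = np.array([gbest[0], gbest[1], gbest[2], L, xp])
                grid.append((fobj(cand), cand))
        grid.sort(key=lambda t: t[0])
        # best grid points that are mutually distant in the (L, x) plane,
        # so competing valleys each contribute a polish start
        picked: list[np.ndarray] = []
        for _, cand in grid:
            if all(abs(cand[3] - p[3]) + abs(cand[4] - p[4]) > 2.0
                   for p in picked):
                picked.append(cand)
            if len(picked) >= 3:
                break
        starts.extend(picked)

        for x0 in starts:
            u0 = (x0 - lo) / span
            res = optimize.minimize(
                fnorm, u0, method="Nelder-Mead",
                options={"maxiter": 1500, "xatol": 1e-10, "fatol": 1e-16,
                         "adaptive": True},
            )
            res = optimize.minimize(
                fnorm, res.x, method="Nelder-Mead",
                options={"maxiter": 500, "xatol": 1e-10, "fatol": 1e-16,
                         "adaptive": True},
            )
            cand = lo + np.clip(res.x, 0.0, 1.0) * span
            val = fobj(cand)
            if val < gbest_val:
                gbest, gbest_val = cand, float(val)

    if gbest[4] >= gbest[3]:
        gbest = gbest.copy()
        gbest[4] = 0.99 * gbest[3]
    return IbifParams.from_array(gbest), gbest_val


# ---------------------------------------------------------------------------
# glottal waveform measures
# ---------------------------------------------------------------------------

def _cycle_bounds(x: np.ndarray, fs: float, f0: float) -> list[tuple[int, int]]:
    """Cycle boundaries at the waveform minima between successive peaks."""
    period = fs / f0
    peaks, _ = find_peaks(x, distance=max(2, int(0.8 * period)),
                          prominence=0.25 * np.ptp(x))
    if len(peaks) < 4:
        return []
    bounds = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        bounds.append(p0 + int(np.argmin(x[p0:p1])))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _cross_up(x: np.ndarray, thr: float, i0: int, i1: int) -> float | None:
    """First upward threshold crossing in [i0, i1), linearly interpolated."""
    seg = x[i0:i1]
    idx = np.flatnonzero((seg[:-1] < thr) & (seg[1:] >= thr))
    if len(idx) == 0:
        return None
    i = idx[0]
    frac = (thr - seg[i]) / (seg[i + 1] - seg[i])
    return i0 + i + float(frac)


def _cross_down(x: np.ndarray, thr: float, i0: int, i1: int) -> float | None:
    """Last downward threshold crossing in [i0, i1), linearly interpolated."""
    seg = x[i0:i1]
    idx = np.flatnonzero((seg[:-1] >= thr) & (seg[1:] < thr))
    if len(idx) == 0:
        return None
    i = idx[-1]
    frac = (seg[i] - thr) / (seg[i] - seg[i + 1])
    return i0 + i + float(frac)


def time_domain_features(
    g: GlottalWaveform,
    open_threshold: float = OPEN_PHASE_THRESHOLD,
) -> GlottalFeatures:
    """Per-cycle ACFL, MFDR, OQ, SQ and NAQ, averaged over complete cycles.

    The open phase of a cycle runs from the upward crossing of
    (cycle minimum + `open_threshold` x cycle peak-to-peak) to the downward
    crossing of the same level; the opening/closing split is at the cycle's
    flow maximum.  MFDR is reported as a magnitude in L/s^2.
    """
    x = g.flow
    fs = g.fs
    if not math.isfinite(g.f0) or g.f0 <= 0:
        raise UndefinedFeaturesError("f0 required for cycle parsing")
    cycles = _cycle_bounds(x, fs, g.f0)
    if len(cycles) < 3:
        raise UndefinedFeaturesError("fewer than 3 complete cycles")

    acfl, mfdr_raw, oq, sq, naq, topen, tclosed = [], [], [], [], [], [], []
    for c0, c1 in cycles:
        cyc = x[c0:c1]
        period = (c1 - c0) / fs
        p2p = float(np.ptp(cyc))
        if p2p <= 0 or period <= 0:
            continue
        thr = float(np.min(cyc)) + open_threshold * p2p
        pk = c0 + int(np.argmax(cyc))
        t_on = _cross_up(x, thr, c0, pk + 1)
        t_off = _cross_down(x, thr, pk, c1)
        d = np.diff(x[c0:c1 + 1]) * fs          # mL/s^2
        mf = float(-np.min(d))
        if t_on is None or t_off is None or mf <= 0:
            continue
        t_o = (t_off - t_on) / fs
        t_rise = (pk - t_on) / fs
        t_fall = (t_off - pk) / fs
        if t_fall <= 0 or t_o <= 0:
            continue
        acfl.append(p2p)
        mfdr_raw.append(mf)
        oq.append(100.0 * t_o / period)
        sq.append(100.0 * t_rise / t_fall)
        naq.append((p2p / mf) / period)
        topen.append(t_o)
        tclosed.append(period - t_o)

    if len(acfl) < 3:
        raise UndefinedFeaturesError("fewer than 3 measurable cycles")
    return GlottalFeatures(
        acfl=float(np.mean(acfl)),
        mfdr=float(np.mean(mfdr_raw)) / MLS2_PER_LS2,
        oq=float(np.mean(oq)),
        sq=float(np.mean(sq)),
        naq=float(np.mean(naq)),
        f0=g.f0,
        t_open=float(np.mean(topen)),
        t_closed=float(np.mean(tclosed)),
    )


def spectral_features(
    g: GlottalWaveform,
    n_harmonics: int = 8,
    hrf_literal: bool = False,
) -> tuple[float, float]:
    """H1-H2 (dB) and HRF (dB) from interpolated-DFT harmonic magnitudes.

    HRF defaults to the conventional 10*log10(sum_{k=2..8} P_k / P_1); the
    literal reading of the published wording (sum of the first eight
    harmonic log-magnitudes over H1) is available via `hrf_literal`.
    Harmonics above Nyquist are skipped (the result is flagged by returning
    over the available harmonics only).
    """
    x = g.flow
    fs, f0 = g.fs, g.f0
    if not math.isfinite(f0) or f0 <= 0:
        raise UndefinedFeaturesError("f0 required for harmonic analysis")
    if len(x) < 4 * fs / f0:
        raise InsufficientDataError("window shorter than 4 periods")
    n = len(x)
    w = np.hanning(n)
    nfft = 1 << int(np.ceil(np.log2(8 * n)))
    spec = np.abs(rfft(x * w, nfft))
    freqs = rfftfreq(nfft, 1.0 / fs)
    df = freqs[1]

    amps = []
    for k in range(1, n_harmonics + 1):
        fk = k * f0
        if fk >= fs / 2:
            break
        i0 = int((fk - f0 / 4) / df)
        i1 = int((fk + f0 / 4) / df) + 1
        i = i0 + int(np.argmax(spec[i0:i1]))
        # parabolic refinement of the peak magnitude
        if 0 < i < len(spec) - 1:
            a, b, c = spec[i - 1], spec[i], spec[i + 1]
            denom = a - 2 * b + c
            if denom != 0:
                d = 0.5 * (a - c) / denom
                b = b - 0.25 * (a - c) * d
            amps.append(max(float(b), 0.0))
        else:
            amps.append(float(spec[i]))
    if len(amps) < 2:
        raise UndefinedFeaturesError("fewer than 2 harmonics below Nyquist")

    amps = np.array(amps) + 1e-300
    h_db = 20.0 * np.log10(amps)
    h1h2 = float(h_db[0] - h_db[1])
    if hrf_literal:
        hrf = float(np.sum(h_db) - h_db[0])
    else:
        p = amps**2
        hrf = float(10.0 * np.log10(np.sum(p[1:]) / p[0]))
    return h1h2, hrf


def validity_filter(feats: GlottalFeatures, f0: float) -> tuple[bool, list[str]]:
    """Physiological-range screen applied before Ps regression.

    Keep iff ACFL >= 1 mL/s, MFDR >= 1 L/s^2, OQ within 0-100 %, and
    f0 <= 500 Hz; NaN values fail their rule.
    """
    reasons = []
    if not (feats.acfl >= 1.0):
        reasons.append("ACFL")
    if not (feats.mfdr >= 1.0):
        reasons.append("MFDR")
    if not (0.0 <= feats.oq <= 100.0):
        reasons.append("OQ")
    if not (f0 <= 500.0):
        reasons.append("F0")
    return len(reasons) == 0, reasons
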