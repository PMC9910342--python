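"""The three subglottal-pressure estimators.

Method 1 is the empirical SPL/f0 formula (fixed published constants, output
in kPa, converted to cm H2O here).  Method 2 is the person-specific line
between ACC RMS and reference Ps.  Method 3 is a forward-stepwise multiple
regression over the ten vocal-function measures with partial-F screening,
evaluated by five-fold cross-validation; the fold with the lowest test RMSE
supplies the deployed model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, MissingFeatureError

#: 1 kPa expressed in cm of water (at 4 degC)
KPA_TO_CMH2O = 10.1972

#: nominal speaking f0 (Hz) by sex for Method 1
FO_NOMINAL = {"male": 120.0, "female": 190.0}

#: canonical order of the ten vocal-function measures (tie-break order too)
FEATURE_ORDER = ["RMS", "F0", "CPP", "ACFL", "MFDR",
                 "OQ", "SQ", "H1H2", "HRF", "NAQ"]


@dataclass(frozen=True)
class Method1Params:
    c0: float = 0.14          # kPa
    c1: float = 0.06          # kPa
    spl_ref: float = 88.5     # dB
    spl_scale: float = 27.3   # dB per decade
    fo_nominal: float = 120.0  # Hz


def kpa_to_cmh2o(x):
    """Convert kPa to cm H2O (1 kPa = 10.1972 cm H2O)."""
    return np.asarray(x, dtype=float) * KPA_TO_CMH2O if np.ndim(x) else x * KPA_TO_CMH2O


def ps_method1(spl, f0, fo_nominal: float, params: Method1Params | None = None):
    """Empirical Ps estimate, returned in cm H2O.

    Ps[kPa] = c0 + c1*(f0/foN)^2 + 10^((SPL - spl_ref)/spl_scale), with the
    published constants c0=0.14, c1=0.06, spl_ref=88.5 dB, spl_scale=27.3 dB.
    """
    p = params or Method1Params(fo_nominal=fo_nominal)
    spl = np.asarray(spl, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    ps_kpa = p.c0 + p.c1 * (f0 / fo_nominal) ** 2 \
        + 10.0 ** ((spl - p.spl_ref) / p.spl_scale)
    out = ps_kpa * KPA_TO_CMH2O
    return float(out) if out.ndim == 0 else out


@dataclass
class LineModel:
    """Method 2: Ps[cm H2O] = slope * ACCrms + intercept."""

    slope: float
    intercept: float
    n_points: int = 0
    flags: list[str] = field(default_factory=list)


def fit_method2(acc_rms: np.ndarray, ps_ref: np.ndarray) -> LineModel:
    """Ordinary least squares line between ACC RMS and reference Ps."""
    x = np.asarray(acc_rms, dtype=float)
    y = np.asarray(ps_ref, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 paired points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in acc_rms")
    slope, intercept = np.polyfit(x, y, 1)
    flags = [] if len(x) >= 10 else ["few_points"]
    return LineModel(float(slope), float(intercept), n_points=len(x), flags=flags)


def predict_method2(model: LineModel, acc_rms) -> np.ndarray:
    out = model.slope * np.asarray(acc_rms, dtype=float) + model.intercept
    return float(out) if out.ndim == 0 else out


@dataclass
class StepwiseModel:
    """Method 3: forward-stepwise multiple regression over the ten measures."""

    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    screening_alpha: float = 0.05
    fold_rmses: list[float] | None = None
    chosen_fold: int | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "method": 3,
            "features": self.selected_features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "alpha": self.screening_alpha,
            "fold_rmses": self.fold_rmses,
            "chosen_fold": self.chosen_fold,
            "seed": self.seed,
            "flags": self.flags,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StepwiseModel":
        d = json.loads(Path(path).read_text())
        return cls(d["features"], d["coefficients"], d["intercept"],
                   d.get("alpha", 0.05), d.get("fold_rmses"),
                   d.get("chosen_fold"), d.get("seed"), d.get("flags", []))


def _as_matrix(features, feature_names) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        names = [c for c in FEATURE_ORDER if c in features.columns] \
            if feature_names is None else list(feature_names)
        return features[names].to_numpy(dtype=float), names
    X = np.asarray(features, dtype=float)
    if feature_names is None:
        feature_names = FEATURE_ORDER[: X.shape[1]]
    return X, list(feature_names)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coefs incl. intercept, RSS)."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def fit_method3_stepwise(
    features,
    ps_ref: np.ndarray,
    alpha: float = 0.05,
    feature_names: list[str] | None = None,
) -> StepwiseModel:
    """Forward stepwise selection with a partial-F entry screen.

    At each step, each remaining candidate is tentatively added to the OLS
    model; the candidate with the smallest partial-F p-value enters if that
    p-value is below alpha / (number of candidates screened this step)
    (Bonferroni over the per-step screen, which keeps the per-step
    false-entry probability at ~alpha; ties broken by larger F, then the
    canonical measure order).  Stops when no candidate qualifies or the
    residual sum of squares is numerically exhausted.  If no feature ever
    passes, an intercept-only model is returned with a warning flag.
    """
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(ps_ref, dtype=float)
    n = len(y)
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    _, rss0 = _ols(X[:, []], y)
    rss_floor = 1e-10 * (rss0 + 1e-30)

    while remaining and rss0 > rss_floor:
        best = None  # (pval, -F, order, j, rss1)
        for j in remaining:
            cols = selected + [j]
            if np.ptp(X[:, j]) == 0:
                continue
            _, rss1 = _ols(X[:, cols], y)
            dof = n - len(cols) - 1
            if dof <= 0 or rss1 <= 0:
                continue
            fstat = (rss0 - rss1) / (rss1 / dof)
            pval = float(stats.f.sf(fstat, 1, dof))
            if best is None or (pval, -fstat, j) < (best[0], -best[1], best[3]):
                best = (pval, fstat, rss1, j)
        if best is None or best[0] >= alpha / max(1, len(remaining)):
            break
        selected.append(best[3])
        remaining.remove(best[3])
        rss0 = best[2]

    flags = []
    if not selected:
        flags.append("intercept_only")
        return StepwiseModel([], {}, float(np.mean(y)), alpha, flags=flags)
    coef, _ = _ols(X[:, selected], y)
    sel_names = [names[j] for j in selected]
    return StepwiseModel(
        selected_features=sel_names,
        coefficients={nm: float(c) for nm, c in zip(sel_names, coef[1:])},
        intercept=float(coef[0]),
        screening_alpha=alpha,
        flags=flags,
    )


def crossvalidate_method3(
    features,
    ps_ref: np.ndarray,
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    feature_names: list[str] | None = None,
) -> StepwiseModel:
    """k-fold cross-validated stepwise fit; returns the best-fold model.

    Folds are disjoint, sized within one of each other, formed by a seeded
    random permutation.  The stepwise model is refit on each training split
    and scored by RMSE on its test split; the returned model is the fit from
    the fold with the minimum test RMSE, carrying all fold RMSEs.
    """
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(ps_ref, dtype=float)
    n = len(y)
    flags = []
    if n < 5 * k:
        k = max(2, n // 5)
        flags.append("fewer_folds")
        warnings.warn(f"too few segments; falling back to {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    models, rmses = [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        m = fit_method3_stepwise(X[train_idx], y[train_idx], alpha, names)
        pred = _predict_matrix(m, X[test_idx], names)
        rmses.append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))
        models.append(m)
    chosen = int(np.argmin(rmses))
    model = models[chosen]
    model.fold_rmses = rmses
    model.chosen_fold = chosen
    model.seed = seed
    model.flags = flags + model.flags
    return model


def _predict_matrix(model: StepwiseModel, X: np.ndarray, names: list[str]) -> np.ndarray:
    out = np.full(X.shape[0], model.intercept, dtype=float)
    for nm, c in model.coefficients.items():
        out += c * X[:, names.index(nm)]
    return out


def predict_ps(model, features) -> np.ndarray:
    """Predict Ps (cm H2O) from a LineModel or StepwiseModel.

    `features` is a DataFrame (or mapping) containing the model's selected
    feature columns; for a LineModel, the ``RMS`` column is used.
    Missing features raise :class:`MissingFeatureError`.  Predictions are
    not clipped; negative estimates are the caller's to flag.
    """
    if isinstance(model, LineModel):
        if isinstance(features, pd.DataFrame):
            if "RMS" not in features.columns:
                raise MissingFeatureError("RMS")
            return predict_method2(model, features["RMS"].to_numpy(dtype=float))
        return predict_method2(model, np.asarray(features, dtype=float))
    if isinstance(features, dict):
        features = pd.DataFrame({k: np.atleast_1d(v) for k, v in features.items()})
    for nm in model.selected_features:
        if nm not in features.columns:
            raise MissingFeatureError(nm)
    out = np.full(len(features), model.intercept, dtype=float)
    for nm, c in model.coefficients.items():
        out += c * features[nm].to_numpy(dtype=float)
    return out
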