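import numpy as np
import pandas as pd
import pytest

from vocalps.errors import DegenerateFitError, MissingFeatureError
from vocalps.ps_models import (
    FEATURE_ORDER,
    KPA_TO_CMH2O,
    LineModel,
    StepwiseModel,
    crossvalidate_method3,
    fit_method2,
    fit_method3_stepwise,
    kpa_to_cmh2o,
    predict_method2,
    predict_ps,
    ps_method1,
)


class TestMethod1:
    def test_nominal_point(self):
        # f0 = foN and SPL = 88.5 -> 0.14 + 0.06 + 1 = 1.2 kPa
        assert ps_method1(88.5, 120.0, 120.0) == pytest.approx(
            1.2 * KPA_TO_CMH2O, abs=1e-9)

    def test_low_spl_limit(self):
        ps = ps_method1(-200.0, 190.0, 190.0)
        assert ps == pytest.approx((0.14 + 0.06) * KPA_TO_CMH2O, abs=1e-6)

    def test_one_decade_spl(self):
        # SPL = 88.5 + 27.3 -> exponent 1 -> 0.14 + 0.06 + 10 = 10.2 kPa
        assert ps_method1(88.5 + 27.3, 120.0, 120.0) == pytest.approx(
            10.2 * KPA_TO_CMH2O, abs=1e-9)

    def test_monotone_in_spl_and_f0(self):
        spls = np.linspace(50, 110, 40)
        ps = ps_method1(spls, 150.0, 190.0)
        assert np.all(np.diff(ps) > 0)
        f0s = np.linspace(80, 400, 40)
        ps = ps_method1(80.0, f0s, 190.0)
        assert np.all(np.diff(ps) > 0)


class TestKpaConversion:
    @pytest.mark.parametrize("kpa,cm", [(0.0, 0.0), (1.0, 10.1972),
                                        (0.0980665, 1.0)])
    def test_values(self, kpa, cm):
        assert kpa_to_cmh2o(kpa) == pytest.approx(cm, abs=2e-4)


class TestMethod2:
    def test_noiseless_exact(self):
        x = np.linspace(1, 8, 12)
        m = fit_method2(x, 2.0 * x + 3.0)
        assert m.slope == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(3.0, abs=1e-9)

    def test_noisy_slope_within_5pct_median(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(1, 8, 60)
            y = 2.0 * x + 3.0 + rng.normal(0, 0.5, 60)
            errs.append(abs(fit_method2(x, y).slope - 2.0) / 2.0)
        assert np.median(errs) < 0.05

    def test_train_rmse_zero_noiseless(self):
        x = np.linspace(1, 8, 20)
        y = 2.0 * x + 3.0
        m = fit_method2(x, y)
        assert np.sqrt(np.mean((predict_method2(m, x) - y) ** 2)) < 1e-9

    def test_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_method2(np.full(12, 2.0), np.linspace(0, 1, 12))

    def test_few_points_flagged(self):
        m = fit_method2(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        assert "few_points" in m.flags


def _synth_features(rng, n, law):
    """Ten-feature table; `law` maps the feature dict to Ps."""
    X = pd.DataFrame({
        "RMS": rng.uniform(1, 8, n),
        "F0": rng.normal(190, 15, n),
        "CPP": rng.normal(15, 3, n),
        "ACFL": rng.uniform(100, 400, n),
        "MFDR": rng.uniform(100, 500, n),
        "OQ": rng.uniform(40, 70, n),
        "SQ": rng.uniform(110, 250, n),
        "H1H2": rng.normal(8, 3, n),
        "HRF": rng.normal(-8, 3, n),
        "NAQ": rng.uniform(0.1, 0.3, n),
    })
    return X, law(X)


class TestStepwise:
    def test_rms_only_law_selects_rms(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X, y = _synth_features(
                rng, 60, lambda d: 2 * d["RMS"] + rng.normal(0, 0.5, 60))
            m = fit_method3_stepwise(X, y.to_numpy())
            if m.selected_features == ["RMS"]:
                hits += 1
        # per-step family-wise false-entry rate is held at ~alpha, so the
        # exact-selection rate is ~95%; bound leaves room for binomial noise
        assert hits >= 90

    def test_rms_and_oq_law(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X, y = _synth_features(
                rng, 60,
                lambda d: 2 * d["RMS"] + 0.15 * d["OQ"] + rng.normal(0, 0.5, 60))
            m = fit_method3_stepwise(X, y.to_numpy())
            if set(m.selected_features) == {"RMS", "OQ"}:
                hits += 1
        assert hits >= 90

    def test_all_noise_type1_rate(self):
        inclusions = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(2000 + seed)
            X, _ = _synth_features(rng, 60, lambda d: None)
            y = rng.normal(10, 2, 60)
            m = fit_method3_stepwise(X, y)
            inclusions += len(m.selected_features)
        # 10 candidates * alpha=0.05 -> expected first-entry rate ~0.5/run
        # upper-bound with generous slack for stepwise multiplicity
        assert inclusions / (n_runs * 10) <= 0.05 * 2.0

    def test_intercept_only_warning(self):
        rng = np.random.default_rng(3)
        X, _ = _synth_features(rng, 40, lambda d: None)
        y = np.full(40, 7.0) + rng.normal(0, 1e-9, 40)
        m = fit_method3_stepwise(X, y, alpha=1e-12)
        assert m.selected_features == []
        assert "intercept_only" in m.flags

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        X, y = _synth_features(
            rng, 80, lambda d: 2 * d["RMS"] + 0.2 * d["OQ"] + rng.normal(0, 0.3, 80))
        m1 = fit_method3_stepwise(X, y.to_numpy())
        shuffled = X[list(reversed(X.columns))]
        m2 = fit_method3_stepwise(shuffled, y.to_numpy(),
                                  feature_names=list(shuffled.columns))
        assert set(m1.selected_features) == set(m2.selected_features)
        for k in m1.coefficients:
            assert m1.coefficients[k] == pytest.approx(m2.coefficients[k], rel=1e-9)


class TestCrossValidation:
    def test_fold_partition_contract(self):
        rng = np.random.default_rng(5)
        X, y = _synth_features(rng, 53, lambda d: 2 * d["RMS"] + 1)
        m = crossvalidate_method3(X, y.to_numpy(), k=5, seed=0)
        assert len(m.fold_rmses) == 5
        assert m.chosen_fold == int(np.argmin(m.fold_rmses))

    def test_noiseless_linear_truth(self):
        rng = np.random.default_rng(6)
        X, y = _synth_features(rng, 60, lambda d: 2 * d["RMS"] + 3)
        m = crossvalidate_method3(X, y.to_numpy(), k=5, seed=0)
        assert max(m.fold_rmses) < 1e-6
        assert m.selected_features == ["RMS"]
        assert m.coefficients["RMS"] == pytest.approx(2.0, abs=1e-6)

    def test_fewer_folds_fallback(self):
        rng = np.random.default_rng(7)
        X, y = _synth_features(rng, 12, lambda d: 2 * d["RMS"] + 1)
        with pytest.warns(UserWarning):
            m = crossvalidate_method3(X, y.to_numpy(), k=5, seed=0)
        assert "fewer_folds" in m.flags

    def test_method3_beats_method2_with_nonrms_term(self):
        med3, med2 = [], []
        for seed in range(20):
            rng = np.random.default_rng(8000 + seed)
            X, y = _synth_features(
                rng, 60,
                lambda d: 2 * d["RMS"] + 0.2 * d["OQ"] + rng.normal(0, 0.4, 60))
            y = y.to_numpy()
            m3 = crossvalidate_method3(X, y, seed=seed)
            m2 = fit_method2(X["RMS"].to_numpy(), y)
            r2 = np.sqrt(np.mean((predict_method2(m2, X["RMS"].to_numpy()) - y) ** 2))
            med3.append(m3.fold_rmses[m3.chosen_fold])
            med2.append(r2)
        assert np.median(med3) <= np.median(med2)


class TestPredict:
    def test_intercept_only_constant(self):
        m = StepwiseModel([], {}, 9.0)
        out = predict_ps(m, pd.DataFrame({"RMS": [1.0, 5.0]}))
        np.testing.assert_allclose(out, [9.0, 9.0])

    def test_linear_combination(self):
        m = StepwiseModel(["RMS"], {"RMS": 2.0}, 3.0)
        out = predict_ps(m, pd.DataFrame({"RMS": [5.0]}))
        assert out[0] == pytest.approx(13.0)

    def test_missing_feature_raises(self):
        m = StepwiseModel(["OQ"], {"OQ": 1.0}, 0.0)
        with pytest.raises(MissingFeatureError):
            predict_ps(m, pd.DataFrame({"RMS": [1.0]}))

    def test_line_model_path(self):
        m = LineModel(2.0, 3.0)
        out = predict_ps(m, pd.DataFrame({"RMS": [5.0]}))
        assert float(np.asarray(out)[0]) == pytest.approx(13.0)

    def test_end_to_end_rmse_within_2x_noise(self):
        rng = np.random.default_rng(11)
        sigma = 0.5
        X, y = _synth_features(
            rng, 100,
            lambda d: 2 * d["RMS"] + 0.15 * d["OQ"] + rng.normal(0, sigma, 100))
        y = y.to_numpy()
        m = crossvalidate_method3(X[:80], y[:80], seed=0)
        pred = predict_ps(m, X[80:])
        rmse = np.sqrt(np.mean((pred - y[80:]) ** 2))
        assert rmse < 2 * sigma

    def test_json_roundtrip(self, tmp_path):
        m = StepwiseModel(["RMS", "OQ"], {"RMS": 2.0, "OQ": 0.1}, 1.5,
                          fold_rmses=[1, 2, 3, 4, 5], chosen_fold=0, seed=4)
        m.to_json(tmp_path / "m.json")
        back = StepwiseModel.from_json(tmp_path / "m.json")
        assert back.selected_features == m.selected_features
        assert back.coefficients == m.coefficients
        assert back.intercept == m.intercept


def test_feature_order_is_table_order():
    assert FEATURE_ORDER == ["RMS", "F0", "CPP", "ACFL", "MFDR",
                             "OQ", "SQ", "H1H2", "HRF", "NAQ"]
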