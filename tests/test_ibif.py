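import math

import numpy as np
import pytest

from vocalps import ibif, synthetic
from vocalps.errors import InsufficientDataError, InvalidParamsError
from vocalps.ibif import (
    DEFAULT_BOUNDS,
    DEFAULT_PARAMS,
    GlottalFeatures,
    GlottalWaveform,
    IbifParams,
    bandpass,
    fit_ibif_pso,
    forward_filter,
    ibif_objective,
    ibif_transfer,
    inverse_filter,
    spectral_features,
    time_domain_features,
    validity_filter,
)

FS = 20000.0


class TestIbifParams:
    def test_negative_rejected(self):
        with pytest.raises(InvalidParamsError):
            IbifParams(-1, 400, 1e6, 12, 5)

    def test_position_beyond_trachea_rejected(self):
        with pytest.raises(InvalidParamsError):
            IbifParams(1.5, 400, 1e6, 10, 11)


class TestTransfer:
    def test_magnitude_positive_in_band(self):
        h = ibif_transfer(DEFAULT_PARAMS, FS, 2 ** 14)
        f = np.fft.rfftfreq(2 ** 14, 1 / FS)
        band = (f >= 50) & (f <= 4000)
        assert np.all(np.abs(h[band]) > 0)

    def test_doubling_inertance_shifts_resonance_sqrt2(self):
        # resonance f ~ sqrt(k/m): doubling m divides the peak freq by sqrt 2
        n = 2 ** 16
        f = np.fft.rfftfreq(n, 1 / FS)
        band = (f > 50) & (f < 400)
        p2 = IbifParams(2 * DEFAULT_PARAMS.skin_inertance,
                        DEFAULT_PARAMS.skin_resistance,
                        DEFAULT_PARAMS.skin_stiffness,
                        DEFAULT_PARAMS.tracheal_length,
                        DEFAULT_PARAMS.acc_position)
        h1 = np.abs(ibif_transfer(DEFAULT_PARAMS, FS, n))[band]
        h2 = np.abs(ibif_transfer(p2, FS, n))[band]
        f1 = f[band][np.argmax(h1)]
        f2 = f[band][np.argmax(h2)]
        assert f1 / f2 == pytest.approx(math.sqrt(2), rel=0.02)


class TestRoundTrip:
    def test_pulse_train_correlation(self):
        flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.5, FS, 0)
        acc = forward_filter(flow, DEFAULT_PARAMS, FS)
        g = inverse_filter(acc, DEFAULT_PARAMS, FS, f0=150)
        ref = bandpass(flow - flow.mean(), FS, 50, 4000)
        est = bandpass(g.flow, FS, 50, 4000)
        assert np.corrcoef(ref, est)[0, 1] >= 0.99

    def test_random_params_roundtrip_property(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            p = IbifParams(
                rng.uniform(*DEFAULT_BOUNDS["skin_inertance"]),
                rng.uniform(*DEFAULT_BOUNDS["skin_resistance"]),
                rng.uniform(*DEFAULT_BOUNDS["skin_stiffness"]),
                rng.uniform(10.0, 16.0),
                rng.uniform(2.0, 8.0),
            )
            f0 = rng.uniform(100, 250)
            flow, _ = synthetic.lf_pulse_train(f0, 55, 150, 250, 0.4, FS, 0.5,
                                               rng)
            acc = forward_filter(flow, p, FS)
            g = inverse_filter(acc, p, FS, f0=f0)
            ref = bandpass(flow - flow.mean(), FS, 50, 4000)
            est = bandpass(g.flow, FS, 50, 4000)
            assert np.corrcoef(ref, est)[0, 1] >= 0.99

    def test_output_zero_mean(self):
        flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.3, FS, 0)
        acc = forward_filter(flow, DEFAULT_PARAMS, FS)
        g = inverse_filter(acc, DEFAULT_PARAMS, FS)
        assert abs(np.mean(g.flow)) < 1e-6 * np.ptp(g.flow)

    def test_amplitude_linearity(self):
        flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.3, FS, 0)
        acc = forward_filter(flow, DEFAULT_PARAMS, FS)
        g1 = inverse_filter(acc, DEFAULT_PARAMS, FS)
        g2 = inverse_filter(2 * acc, DEFAULT_PARAMS, FS)
        np.testing.assert_allclose(g2.flow, 2 * g1.flow, atol=1e-9)

    def test_oq_recovery(self):
        flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.5, FS, 0)
        acc = forward_filter(flow, DEFAULT_PARAMS, FS)
        g = inverse_filter(acc, DEFAULT_PARAMS, FS, f0=150)
        g.f0 = 150.0
        feats = time_domain_features(g)
        assert feats.oq == pytest.approx(60, abs=5)

    def test_too_short_segment(self):
        with pytest.raises(InsufficientDataError):
            inverse_filter(np.ones(100), DEFAULT_PARAMS, FS, f0=100)


class TestTimeDomainFeatures:
    def test_triangular_pulse(self):
        # symmetric triangle filling half of each period, peak-to-peak 300
        fs, f0, n_cycles = FS, 100.0, 8
        period = int(fs / f0)
        half = period // 2
        quarter = half // 2
        cyc = np.concatenate([
            np.linspace(0, 300, quarter, endpoint=False),
            np.linspace(300, 0, quarter, endpoint=False),
            np.zeros(period - 2 * quarter),
        ])
        x = np.tile(cyc, n_cycles)
        g = GlottalWaveform(x - x.mean(), fs, f0)
        feats = time_domain_features(g)
        assert feats.acfl == pytest.approx(300, rel=0.01)
        # under the symmetric 10% threshold the analytic open phase of the
        # half-period triangle is exactly 45% of the period; SQ is exactly 100
        assert feats.oq == pytest.approx(45, abs=1)
        assert feats.sq == pytest.approx(100, abs=5)

    def test_lf_train_targets(self):
        flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.4, FS, 0)
        g = GlottalWaveform(flow - flow.mean(), FS, 150)
        feats = time_domain_features(g)
        assert feats.oq == pytest.approx(60, abs=5)
        assert feats.sq == pytest.approx(200, abs=15)
        assert feats.acfl == pytest.approx(300, rel=0.01)

    def test_scaling_homogeneity(self):
        flow, _ = synthetic.lf_pulse_train(150, 55, 150, 200, 0.4, FS, 0)
        g1 = GlottalWaveform(flow - flow.mean(), FS, 150)
        g2 = GlottalWaveform(2 * (flow - flow.mean()), FS, 150)
        a, b = time_domain_features(g1), time_domain_features(g2)
        assert b.acfl == pytest.approx(2 * a.acfl, rel=1e-9)
        assert b.mfdr == pytest.approx(2 * a.mfdr, rel=1e-9)
        assert b.oq == pytest.approx(a.oq, rel=1e-9)
        assert b.sq == pytest.approx(a.sq, rel=1e-9)
        assert b.naq == pytest.approx(a.naq, rel=1e-9)

    def test_open_closed_sum_to_period(self):
        flow, _ = synthetic.lf_pulse_train(180, 55, 150, 200, 0.4, FS, 0)
        g = GlottalWaveform(flow - flow.mean(), FS, 180)
        feats = time_domain_features(g)
        assert feats.t_open + feats.t_closed == pytest.approx(1 / 180, rel=0.01)


class TestSpectralFeatures:
    def test_pure_sine_h1h2_large(self):
        t = np.arange(int(0.2 * FS)) / FS
        g = GlottalWaveform(np.sin(2 * np.pi * 150 * t), FS, 150)
        h1h2, hrf = spectral_features(g)
        assert h1h2 >= 40
        assert hrf < -20  # harmonics 2..8 at the floor

    def test_two_tone_6db(self):
        t = np.arange(int(0.2 * FS)) / FS
        x = 1.0 * np.sin(2 * np.pi * 150 * t) + 0.5 * np.sin(2 * np.pi * 300 * t)
        g = GlottalWaveform(x, FS, 150)
        h1h2, _ = spectral_features(g)
        assert h1h2 == pytest.approx(20 * math.log10(2), abs=0.1)

    def test_hrf_literal_switch_differs(self):
        flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.3, FS, 0)
        g = GlottalWaveform(flow - flow.mean(), FS, 150)
        _, hrf_conv = spectral_features(g)
        _, hrf_lit = spectral_features(g, hrf_literal=True)
        assert hrf_conv != hrf_lit


class TestValidityFilter:
    def test_low_acfl_dropped(self):
        f = GlottalFeatures(acfl=0.5, mfdr=100, oq=50, sq=150, naq=0.1)
        keep, reasons = validity_filter(f, 150)
        assert not keep and reasons == ["ACFL"]

    def test_high_f0_dropped(self):
        f = GlottalFeatures(acfl=200, mfdr=100, oq=50, sq=150, naq=0.1)
        keep, reasons = validity_filter(f, 600)
        assert not keep and reasons == ["F0"]

    def test_all_rules_pass(self):
        f = GlottalFeatures(acfl=200, mfdr=300, oq=55, sq=150, naq=0.1)
        keep, reasons = validity_filter(f, 180)
        assert keep and reasons == []

    def test_nan_fails(self):
        f = GlottalFeatures()
        keep, reasons = validity_filter(f, 180)
        assert not keep
        assert {"ACFL", "MFDR", "OQ"} <= set(reasons)

    def test_noiseless_modal_session_keep_rate_one(self):
        flow, _ = synthetic.lf_pulse_train(180, 55, 150, 250, 0.4, FS, 0)
        acc = forward_filter(flow, DEFAULT_PARAMS, FS)
        g = inverse_filter(acc, DEFAULT_PARAMS, FS, f0=180)
        g.f0 = 180.0
        feats = time_domain_features(g)
        keep, _ = validity_filter(feats, 180)
        assert keep


@pytest.fixture(scope="module")
def planted():
    flow, _ = synthetic.lf_pulse_train(150, 60, 200, 300, 0.4, FS, 0.3)
    true = IbifParams(1.5, 400.0, 1.3e6, 12.0, 5.0)
    acc = forward_filter(flow, true, FS)
    return flow, acc, true


class TestPsoFit:
    def test_planted_objective_recovery(self, planted):
        flow, acc, true = planted
        j_true = ibif_objective(true.as_array(), acc, flow, FS,
                                dict(DEFAULT_BOUNDS))
        _, j = fit_ibif_pso(acc, flow, FS, swarm_size=25, n_iter=50, seed=1)
        assert j <= 1.01 * j_true

    def test_bounds_respected(self, planted):
        flow, acc, _ = planted
        params, _ = fit_ibif_pso(acc, flow, FS, swarm_size=8, n_iter=5,
                                 seed=2, polish=False)
        for name, (lo, hi) in DEFAULT_BOUNDS.items():
            assert lo <= getattr(params, name) <= hi

    def test_deterministic_given_seed(self, planted):
        flow, acc, _ = planted
        p1, j1 = fit_ibif_pso(acc, flow, FS, swarm_size=8, n_iter=5, seed=3,
                              polish=False)
        p2, j2 = fit_ibif_pso(acc, flow, FS, swarm_size=8, n_iter=5, seed=3,
                              polish=False)
        assert p1 == p2
        assert j1 == j2
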