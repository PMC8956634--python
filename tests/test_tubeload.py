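"""Tube + Windkessel model algebra and the transit-time fit."""

import cmath
import math

import numpy as np
import pytest

from cfpwv.signals import Beat, Waveform, add_gaussian_noise
from cfpwv.tubeload import (
    FitBounds,
    MultistartGrid,
    TubeGeometry,
    TubeLoadParams,
    characteristic_impedance,
    fit_beat_pair,
    fit_dual_tube,
    fit_single_tube,
    predict_distal,
    propagate_beat,
    propagation_time,
    pwv_from_ptt,
    reflection_coefficient,
    transfer_function,
    transfer_gain,
)

from conftest import synthetic_beat


class TestGeometry:
    GEO = TubeGeometry(rho=1050.0, L=0.6, A=3.14e-4, C_tube=1e-8)

    def test_characteristic_impedance_value(self):
        expect = math.sqrt(1050.0 * 0.6 / (3.14e-4 * 1e-8))
        assert characteristic_impedance(self.GEO) == pytest.approx(expect, rel=1e-12)

    def test_propagation_time_value(self):
        expect = math.sqrt(1050.0 * 0.6 * 1e-8 / 3.14e-4)
        assert propagation_time(self.GEO) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("field, factor", [("A", 4.0), ("C_tube", 4.0)])
    def test_quadrupling_halves_impedance(self, field, factor):
        import dataclasses

        scaled = dataclasses.replace(self.GEO, **{field: getattr(self.GEO, field) * factor})
        assert characteristic_impedance(scaled) == pytest.approx(
            characteristic_impedance(self.GEO) / 2.0
        )

    def test_quadrupling_length_doubles_time(self):
        import dataclasses

        scaled = dataclasses.replace(self.GEO, L=self.GEO.L * 4)
        assert propagation_time(scaled) == pytest.approx(2 * propagation_time(self.GEO))

    def test_time_equals_impedance_times_compliance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = TubeGeometry(
                rho=rng.uniform(900, 1100),
                L=rng.uniform(0.1, 1.0),
                A=rng.uniform(1e-5, 1e-3),
                C_tube=rng.uniform(1e-10, 1e-7),
            )
            assert propagation_time(g) == pytest.approx(
                characteristic_impedance(g) * g.C_tube, rel=1e-12
            )

    def test_nonpositive_fields_error(self):
        with pytest.raises(ValueError):
            TubeGeometry(rho=0.0, L=0.6, A=1e-4, C_tube=1e-8)


class TestReflectionCoefficient:
    def test_dc_value(self):
        p = TubeLoadParams(0.08, 1.2, 0.02)
        g0 = reflection_coefficient(0.0, p)
        assert g0 == pytest.approx(1.2 / (1.2 + 0.04))
        assert g0.imag == 0.0

    def test_total_reflection_limit(self):
        p = TubeLoadParams(0.08, 1e9, 0.02)
        assert abs(reflection_coefficient(0.0, p)) == pytest.approx(1.0, abs=1e-7)

    def test_matched_termination(self):
        p = TubeLoadParams(0.08, 0.0, 0.02)
        omega = np.linspace(0, 200, 50)
        np.testing.assert_array_equal(reflection_coefficient(omega, p), 0.0)

    def test_magnitude_bounded_and_decreasing(self):
        rng = np.random.default_rng(9)
        omega = np.linspace(0.0, 300.0, 200)
        for _ in range(50):
            p = TubeLoadParams(
                rng.uniform(0.01, 0.3), rng.uniform(0.05, 3.0), rng.uniform(0.002, 0.1)
            )
            mag = np.abs(reflection_coefficient(omega, p))
            assert np.all(mag <= 1.0 + 1e-12)
            assert np.all(np.diff(mag) <= 1e-12)


class TestTransferFunction:
    def test_unity_at_dc(self):
        rng = np.random.default_rng(4)
        omega = np.concatenate([[0.0], np.linspace(0.1, 200, 99)])
        for _ in range(100):
            p = TubeLoadParams(
                rng.uniform(0.01, 0.3), rng.uniform(0.0, 3.0), rng.uniform(0.002, 0.1)
            )
            spec = transfer_function(omega, p)
            assert abs(spec.H[0] - 1.0) < 1e-12

    def test_matched_load_is_pure_delay(self):
        p = TubeLoadParams(0.08, 0.0, 0.02)
        omega = np.linspace(0, 250, 100)
        h = transfer_gain(omega, p)
        np.testing.assert_allclose(np.abs(h), 1.0, atol=1e-9)
        expect_phase = np.exp(-1j * omega * 0.08)
        np.testing.assert_allclose(h, expect_phase, atol=1e-9)

    def test_grid_must_include_zero(self):
        with pytest.raises(ValueError):
            transfer_function(np.linspace(1, 10, 5), TubeLoadParams(0.08, 1.0, 0.02))

    def test_matches_scalar_complex_arithmetic_oracle(self):
        # independent term-by-term evaluation with python scalars
        rng = np.random.default_rng(12)
        for _ in range(20):
            td = rng.uniform(0.01, 0.3)
            rc = rng.uniform(0.0, 3.0)
            zc = rng.uniform(0.002, 0.1)
            w = rng.uniform(0.0, 300.0)
            p = TubeLoadParams(td, rc, zc)
            gamma = rc / (rc + 2 * zc + 1j * w * 2 * rc * zc)
            expect = (1 + gamma) / (cmath.exp(1j * w * td) + gamma * cmath.exp(-1j * w * td))
            got = complex(transfer_gain(np.array([w]), p)[0])
            assert got == pytest.approx(expect, rel=1e-12)


class TestPredictDistal:
    def test_matched_load_is_circular_delay(self):
        b = synthetic_beat()
        p = TubeLoadParams(0.080, 0.0, 0.02)
        out = predict_distal(b, p)
        np.testing.assert_allclose(
            out.samples, np.roll(b.samples, int(0.080 * b.fs)), atol=1e-8
        )

    def test_mean_preserved(self):
        b = synthetic_beat()
        for p in [TubeLoadParams(0.05, 1.0, 0.02), TubeLoadParams(0.12, 0.3, 0.08)]:
            out = predict_distal(b, p)
            assert out.samples.mean() == pytest.approx(b.samples.mean(), rel=1e-12)

    def test_beats_shorter_than_quarter_second_rejected(self):
        with pytest.raises(ValueError):
            Beat(np.ones(300), fs=2000.0, onset_time=0.0)


class TestFit:
    def test_forward_then_fit_recovers_parameters(self):
        b = synthetic_beat()
        theta = TubeLoadParams(0.08, 1.2, 0.02)
        dist = propagate_beat(b.samples, b.fs, theta)
        params, rss, conv, pinned = fit_beat_pair(b.samples, dist, b.fs)
        assert conv and not pinned
        assert abs(params.td - 0.08) < 1e-3
        assert rss < 1e-10

    def test_identical_beats_drive_delay_to_zero(self):
        b = synthetic_beat()
        bounds = FitBounds(td=(1e-4, 0.3))
        params, rss, _, pinned = fit_beat_pair(b.samples, b.samples, b.fs, bounds=bounds)
        assert params.td <= 2e-4  # pinned at the (near-zero) lower bound
        assert rss < 1e-6
        assert pinned

    def test_noisy_recovery_median_under_2ms(self):
        b = synthetic_beat()
        theta = TubeLoadParams(0.08, 1.2, 0.02)
        dist = propagate_beat(b.samples, b.fs, theta)
        errs = []
        for i in range(20):
            noisy = add_gaussian_noise(Waveform(dist, fs=b.fs), 20.0, seed=500 + i)
            params, *_ = fit_beat_pair(b.samples, noisy.samples, b.fs)
            errs.append(abs(params.td - 0.08) * 1000)
        assert np.median(errs) <= 2.0

    def test_single_tube_wrapper_averages_beats(self):
        prox = [synthetic_beat(period=0.85 + 0.02 * i) for i in range(3)]
        theta = TubeLoadParams(0.06, 0.8, 0.03)
        dist = [
            Beat(propagate_beat(b.samples, b.fs, theta), fs=b.fs, onset_time=b.onset_time)
            for b in prox
        ]
        res = fit_single_tube(prox, dist)
        assert res.converged
        assert len(res.per_beat) == 3
        assert res.params.td == pytest.approx(0.06, abs=1e-3)

    def test_dual_tube_difference_and_symmetry(self):
        aortic = [synthetic_beat(period=0.9)]
        th_c = TubeLoadParams(0.02, 0.2, 0.08)
        th_f = TubeLoadParams(0.10, 0.2, 0.08)
        carotid = [predict_distal(aortic[0], th_c)]
        femoral = [predict_distal(aortic[0], th_f)]
        ac, af, cf = fit_dual_tube(aortic, carotid, femoral)
        assert ac == pytest.approx(0.02, abs=1e-3)
        assert af == pytest.approx(0.10, abs=1e-3)
        assert cf == pytest.approx(0.08, abs=1e-3)
        # swapping the tubes leaves the absolute difference unchanged
        ac2, af2, cf2 = fit_dual_tube(aortic, femoral, carotid)
        assert cf2 == pytest.approx(cf, abs=2e-3)

    def test_carotid_equal_aortic_gives_afptt(self):
        aortic = [synthetic_beat(period=0.9)]
        th_f = TubeLoadParams(0.10, 0.2, 0.08)
        femoral = [predict_distal(aortic[0], th_f)]
        bounds = FitBounds(td=(1e-4, 0.3))
        _, af, cf = fit_dual_tube(aortic, aortic, femoral, bounds=bounds)
        assert cf == pytest.approx(af, abs=1e-3)


class TestPWV:
    def test_reference_values(self):
        assert pwv_from_ptt(0.75, 0.080) == pytest.approx(7.5)
        assert pwv_from_ptt(0.75, 0.080, factor=1.0) == pytest.approx(9.375)
        assert pwv_from_ptt(0.75, 0.160) == pytest.approx(3.75)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pwv_from_ptt(0.75, 0.0)
        with pytest.raises(ValueError):
            pwv_from_ptt(-1.0, 0.08)
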