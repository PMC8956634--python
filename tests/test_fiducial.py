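"""Fiducial-point primitives and the three comparator PTT estimators."""

import numpy as np
import pytest
from scipy import stats as sst

from cfpwv.fiducial import (
    diastolic_minimum,
    foot_intersecting_tangent,
    matching_shift,
    max_first_derivative,
    ptt_cross_correlation,
    ptt_intersecting_tangent,
    ptt_waveform_matching,
    xcorr_shift,
)
from cfpwv.signals import Beat, Waveform

from conftest import synthetic_beat

FS = 1000.0


def beat(samples, fs=FS, onset=0.0):
    return Beat(np.asarray(samples, dtype=float), fs=fs, onset_time=onset)


class TestDiastolicMinimum:
    def test_parabola_vertex(self):
        t = np.arange(1000) / FS
        b = beat((t - 0.2) ** 2 + 1.0)
        assert diastolic_minimum(b) == pytest.approx(0.2, abs=1e-9)

    def test_tie_goes_to_earlier(self):
        y = np.ones(1000)
        y[100] = y[200] = 0.0
        y[600:] = 2.0  # make beat non-flat
        assert diastolic_minimum(beat(y)) == pytest.approx(0.1)

    def test_flat_beat_errors(self):
        with pytest.raises(ValueError, match="flat"):
            diastolic_minimum(beat(np.ones(500)))


class TestMaxFirstDerivative:
    def test_linear_upstroke_first_sample(self):
        # exactly representable slope so the ramp is a true floating-point tie
        y = np.concatenate([np.zeros(100), np.arange(400) / 64.0])
        t = max_first_derivative(beat(y), smooth_ms=0.0)
        # every ramp sample maximizes the slope; the first one wins the tie
        assert t <= 0.102

    def test_sigmoid_inflection(self):
        t = np.arange(900) / FS
        y = 1.0 / (1.0 + np.exp(-(t - 0.35) / 0.02))
        y[: int(0.1 * FS)] = y[int(0.1 * FS)]  # flat early diastole
        found = max_first_derivative(beat(y), smooth_ms=0.0)
        assert found == pytest.approx(0.35, abs=0.002)

    def test_sine_segment_max_slope_at_zero_crossing(self):
        t = np.arange(1000) / FS
        y = np.sin(2 * np.pi * 1.0 * (t - 0.25))  # min at t=0, max at t=0.5
        found = max_first_derivative(beat(y), smooth_ms=0.0)
        assert found == pytest.approx(0.25, abs=0.002)

    def test_no_upstroke_errors(self):
        y = np.concatenate([np.full(300, 1.0), np.zeros(300)])  # only decline
        with pytest.raises(ValueError, match="upstroke"):
            max_first_derivative(beat(y), smooth_ms=0.0)


class TestIntersectingTangentFoot:
    def test_flat_then_ramp_foot_at_onset(self):
        y = np.concatenate([np.zeros(200), np.arange(300) * 0.02])
        foot = foot_intersecting_tangent(beat(y), smooth_ms=0.0)
        assert foot == pytest.approx(0.200, abs=1.5e-3)

    def test_parabolic_upstroke_half_width(self):
        # p(t) = (t - t0)^2 on [t0, t0+T]: tangent at the end crosses 0 at t0 + T/2
        t0, T = 0.1, 0.4
        t = np.arange(int((t0 + T) * FS) + 1) / FS
        y = np.where(t < t0, 0.0, (t - t0) ** 2)
        foot = foot_intersecting_tangent(beat(y), smooth_ms=0.0, search_frac=0.3)
        assert foot == pytest.approx(t0 + T / 2, abs=2e-3)

    def test_vertical_shift_invariance(self):
        b = synthetic_beat()
        b_shift = Beat(b.samples + 37.0, fs=b.fs, onset_time=b.onset_time)
        assert foot_intersecting_tangent(b) == pytest.approx(
            foot_intersecting_tangent(b_shift), abs=1e-12
        )


class TestWaveformMatching:
    def test_pure_delay_recovered_with_zero_sse(self):
        b = synthetic_beat()
        d = synthetic_beat(delay=0.080)
        shift, sse = matching_shift(b, d)
        assert shift == pytest.approx(0.080, abs=1e-9)
        assert sse == pytest.approx(0.0, abs=1e-18)

    def test_gain_invariance(self):
        b = synthetic_beat()
        d = synthetic_beat(delay=0.080)
        d2 = Beat(2.0 * d.samples, fs=d.fs, onset_time=d.onset_time)
        assert matching_shift(b, d2)[0] == pytest.approx(0.080, abs=1e-9)

    def test_matches_brute_force_sse_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(4):
            b = synthetic_beat(period=0.8 + 0.1 * trial)
            noise = rng.normal(0, 0.5, b.n)
            d = Beat(
                np.roll(b.samples, rng.integers(20, 150)) + noise,
                fs=b.fs,
                onset_time=0.0,
            )
            shift, _ = matching_shift(b, d, smooth_ms=0.0)
            # independent exhaustive scan
            from cfpwv.fiducial import _minmax

            i_min = int(
                round((diastolic_minimum(b) - b.onset_time) * b.fs)
            )
            i_sl = int(
                round(
                    (max_first_derivative(b, smooth_ms=0.0) - b.onset_time) * b.fs
                )
            )
            half = i_sl - i_min
            idx = np.arange(i_min - half, i_min + half + 1)
            patch = _minmax(b.samples.take(idx, mode="wrap"))
            best, best_sse = None, np.inf
            for s in range(int(0.3 * b.fs) + 1):
                seg = d.samples.take(idx + s, mode="wrap")
                if np.ptp(seg) == 0:
                    continue
                sse = float(np.sum((_minmax(seg) - patch) ** 2))
                if sse < best_sse - 0.0:
                    best, best_sse = s, sse
            assert shift == pytest.approx(best / b.fs, abs=1e-12)


class TestCrossCorrelation:
    @staticmethod
    def _pair(delay_samples=80, gain=1.0, offset=0.0, n=6000, seed=0):
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.normal(size=n))
        prox = Waveform(base, fs=FS)
        dist = Waveform(gain * np.roll(base, delay_samples) + offset, fs=FS)
        return prox, dist

    def test_pure_delay_and_peak_coefficient(self):
        t = np.arange(8000) / FS
        base = np.sin(2 * np.pi * 1.2 * t) + 0.3 * np.sin(2 * np.pi * 3.7 * t)
        prox = Waveform(base, fs=FS)
        dist = Waveform(np.roll(base, 80), fs=FS)
        shift, r = xcorr_shift(prox, dist)
        assert shift == pytest.approx(0.080, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        t = np.arange(8000) / FS
        base = np.sin(2 * np.pi * 1.2 * t) + 0.3 * np.sin(2 * np.pi * 3.7 * t)
        prox = Waveform(base, fs=FS)
        dist = Waveform(3.0 * np.roll(base, 80) + 5.0, fs=FS)
        shift, _ = xcorr_shift(prox, dist)
        assert shift == pytest.approx(0.080, abs=1e-9)

    def test_matches_brute_force_pearson_oracle(self):
        prox, dist = self._pair(delay_samples=57, seed=5)
        shift, r = xcorr_shift(prox, dist)
        n = prox.n
        start = int(round(0.1 * n))
        length = int(round(0.8 * n))
        w = prox.samples[start : start + length]
        best_r, best_s = -np.inf, None
        for s in range(int(0.3 * FS) + 1):
            if start + s + length > dist.n:
                break
            seg = dist.samples[start + s : start + s + length]
            rr = sst.pearsonr(w, seg).statistic
            if rr > best_r:
                best_r, best_s = rr, s
        assert shift == pytest.approx(best_s / FS, abs=1e-12)
        assert r == pytest.approx(best_r, abs=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            xcorr_shift(Waveform(np.ones(4000), fs=FS), Waveform(np.ones(4000), fs=FS))


class TestPTTEstimators:
    """Cross-method invariants on beat sequences."""

    @staticmethod
    def _beat_pairs(delay=0.08, n_beats=4, gain=1.0, offset=0.0):
        prox = [synthetic_beat(period=0.85 + 0.02 * i) for i in range(n_beats)]
        dist = [
            Beat(
                gain * np.roll(b.samples, int(delay * b.fs)) + offset,
                fs=b.fs,
                onset_time=b.onset_time,
            )
            for b in prox
        ]
        return prox, dist

    @pytest.mark.parametrize("fn", [ptt_intersecting_tangent, ptt_waveform_matching])
    @pytest.mark.parametrize("delay", [0.040, 0.080, 0.120])
    def test_pure_delay_per_beat(self, fn, delay):
        prox, dist = self._beat_pairs(delay=delay)
        res = fn(prox, dist)
        assert res.n_beats == 4
        np.testing.assert_allclose(res.per_beat_ptt, delay, atol=1.5e-3)

    @pytest.mark.parametrize("fn", [ptt_intersecting_tangent, ptt_waveform_matching])
    def test_gain_offset_invariance(self, fn):
        prox, dist = self._beat_pairs(gain=2.5, offset=-30.0)
        res = fn(prox, dist)
        assert res.ptt_mean == pytest.approx(0.080, abs=1.5e-3)

    def test_identical_sequences_give_zero(self):
        prox, _ = self._beat_pairs()
        res = ptt_intersecting_tangent(prox, prox)
        assert res.ptt_mean == pytest.approx(0.0, abs=1e-12)

    def test_unpaired_beats_error_lists_indices(self):
        prox, dist = self._beat_pairs()
        with pytest.raises(ValueError, match="unpaired"):
            ptt_intersecting_tangent(prox, dist[:-1])

    def test_xcorr_on_recordings(self, pure_delay_records):
        _, carotid, femoral, truth = pure_delay_records
        res = ptt_cross_correlation(carotid, femoral)
        assert res.ptt_mean == pytest.approx(truth.cf_ptt_true, abs=1e-3)
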