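"""Waveform containers and preprocessing for tonometric pressure / ECG records.

Pressure waveforms from applanation tonometry are uniformly sampled,
amplitude-uncalibrated signals contaminated by respiratory / motion baseline
drift.  This module holds the basic containers (:class:`Waveform`,
:class:`SiteRecording`, :class:`Beat`) and the preprocessing chain used by
every transit-time estimator: wavelet baseline removal, linear-interpolation
resampling, ECG R-peak detection, beat segmentation, and the heart-rate
matching rule that validates sequential two-site recordings.

All times are in seconds; sample 0 of a waveform sits at ``t0``; beat windows
are half-open ``[R_i, R_{i+1})``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "SiteRecording",
    "Beat",
    "remove_baseline",
    "resample_linear",
    "detect_r_peaks",
    "mean_heart_rate",
    "check_hr_match",
    "add_gaussian_noise",
    "segment_beats",
]


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled scalar signal (pressure or ECG).

    Parameters
    ----------
    samples : ndarray
        Signal values.  Pressure is in arbitrary tonometric units or mmHg;
        ECG in arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float, default 0.0
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("waveform needs at least 2 samples in 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal span ``(n - 1) / fs`` in seconds."""
        return (self.n - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle, windowed ``[R_i, R_{i+1})`` from the opening R peak."""

    samples: np.ndarray
    fs: float
    onset_time: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if samples.size < 0.25 * self.fs:
            raise ValueError(
                f"beat of {samples.size} samples is shorter than 0.25 s at fs={self.fs}"
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.onset_time + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class SiteRecording:
    """One measurement session: pressure + simultaneous ECG + R-peak times."""

    pressure: Waveform
    ecg: Waveform | None
    r_peaks: np.ndarray
    site: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r_peaks, dtype=float)
        object.__setattr__(self, "r_peaks", r)
        if self.ecg is not None:
            if not math.isclose(self.ecg.fs, self.pressure.fs):
                raise ValueError("pressure and ecg must share fs")
            if abs(self.ecg.duration - self.pressure.duration) > 1.5 / self.pressure.fs:
                raise ValueError("pressure and ecg must have equal duration")
        if r.size:
            if np.any(np.diff(r) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            lo = self.pressure.t0 - 0.5 / self.pressure.fs
            hi = self.pressure.t0 + self.pressure.duration + 0.5 / self.pressure.fs
            if r[0] < lo or r[-1] > hi:
                raise ValueError("r_peaks must lie within the recording span")


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def _baseline_level(fs: float, cutoff_hz: float) -> int:
    # approximation band of a level-L DWT spans [0, fs / 2**(L+1)]
    return max(1, math.ceil(math.log2(fs / cutoff_hz) - 1.0))


def remove_baseline(w: Waveform, cutoff_hz: float = 0.5, wavelet: str = "db8") -> Waveform:
    """Remove baseline drift below ``cutoff_hz`` by wavelet decomposition.

    The signal is decomposed with a Daubechies-8 DWT to the depth at which the
    approximation band lies below ``cutoff_hz``; the reconstructed
    approximation (the drift) is subtracted, so the output is the detail
    content above the cutoff with mean approximately zero for drift-only
    signals.
    """
    if cutoff_hz <= 0 or cutoff_hz >= w.fs / 2:
        raise ValueError("cutoff_hz must be in (0, fs/2)")
    wav = pywt.Wavelet(wavelet)
    if w.n < 2 * wav.dec_len:
        raise ValueError("too short: signal shorter than one decomposition support")
    level = _baseline_level(w.fs, cutoff_hz)
    # remove the end-to-end ramp first: periodization sees a continuous
    # signal, so the drift estimate does not ring at the record edges
    edge = max(1, min(w.n // 4, int(round(w.fs / cutoff_hz / 2.0))))
    x0 = float(np.mean(w.samples[:edge]))
    x1 = float(np.mean(w.samples[-edge:]))
    trend = x0 + (x1 - x0) * np.arange(w.n) / max(1, w.n - 1)
    detrended = w.samples - trend
    with warnings.catch_warnings():
        # levels beyond dwt_max_level only incur boundary effects, which is
        # acceptable for a smooth drift estimate
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(detrended, wav, level=level, mode="periodization")
    approx_only = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    baseline = pywt.waverec(approx_only, wav, mode="periodization")[: w.n]
    return w.with_samples(detrended - baseline)


def resample_linear(w: Waveform, fs_out: float) -> Waveform:
    """Resample by piecewise-linear interpolation onto a uniform ``fs_out`` grid.

    The output grid starts at ``t0`` and covers the original span to within
    one output sample.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be > 0")
    if math.isclose(fs_out, w.fs):
        return w
    n_out = int(math.floor(w.duration * fs_out)) + 1
    t_old = np.arange(w.n) / w.fs
    t_new = np.arange(n_out) / fs_out
    out = np.interp(t_new, t_old, w.samples)
    return Waveform(out, fs=fs_out, t0=w.t0)


def detect_r_peaks(
    ecg: Waveform,
    refractory_s: float = 0.25,
    threshold_frac: float = 0.3,
) -> np.ndarray:
    """Detect ECG R-peak times with a Pan-Tompkins-style chain.

    Band-pass (5-15 Hz) -> differentiate -> square -> 150 ms moving-window
    integration -> threshold at ``threshold_frac`` of the integrated maximum,
    with a 250 ms refractory period.  Candidate peaks are refined to the local
    extremum of the band-passed ECG within +-80 ms.

    Returns strictly increasing peak times in seconds.
    """
    if ecg.duration < 2.0:
        raise ValueError("ECG must be at least 2 s long")
    x = ecg.samples - np.mean(ecg.samples)
    if np.ptp(x) == 0:
        raise ValueError("no beats: flat ECG")
    nyq = ecg.fs / 2
    hi = min(15.0, 0.9 * nyq)
    sos = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    diff = np.gradient(bp) * ecg.fs
    sq = diff**2
    win = max(1, int(round(0.150 * ecg.fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    height = threshold_frac * integ.max()
    if height <= 0:
        raise ValueError("no beats: no QRS energy found")
    dist = max(1, int(round(refractory_s * ecg.fs)))
    locs, _ = sps.find_peaks(integ, height=height, distance=dist)
    if locs.size == 0:
        raise ValueError("no beats: no peaks above threshold")
    # refine on the band-passed signal (sign-insensitive)
    half = int(round(0.080 * ecg.fs))
    refined = []
    for i in locs:
        a, b = max(0, i - half), min(ecg.n, i + half + 1)
        refined.append(a + int(np.argmax(np.abs(bp[a:b]))))
    refined = np.unique(refined)
    # re-apply refractory after refinement
    keep: list[int] = []
    for i in refined:
        if not keep or i - keep[-1] >= dist:
            keep.append(int(i))
    return ecg.t0 + np.asarray(keep, dtype=float) / ecg.fs


def mean_heart_rate(r_peaks: np.ndarray) -> float:
    """Mean heart rate in bpm: ``60 / mean(R-R interval)``."""
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 R peaks")
    return 60.0 / float(np.mean(np.diff(r)))


def check_hr_match(hr_a: float, hr_b: float, tol: float = 1.0) -> bool:
    """Sequential-recording validity: mean heart rates within ``tol`` bpm."""
    if hr_a <= 0 or hr_b <= 0:
        raise ValueError("heart rates must be positive")
    return abs(hr_a - hr_b) <= tol


def add_gaussian_noise(w: Waveform, snr_db: float, seed: int) -> Waveform:
    """Add white Gaussian noise at the requested SNR (dB).

    SNR is defined on the mean-removed (AC) signal power, so the arbitrary
    tonometric DC level does not enter.  ``snr_db = inf`` is the no-noise
    sentinel and returns the input unchanged.  Deterministic given ``seed``.
    """
    if np.isinf(snr_db):
        return w
    ac = w.samples - np.mean(w.samples)
    p_sig = float(np.mean(ac**2))
    if p_sig == 0:
        raise ValueError("signal has zero AC power")
    p_noise = p_sig / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, math.sqrt(p_noise), size=w.n)
    return w.with_samples(w.samples + noise)


def segment_beats(rec: SiteRecording, min_beat_s: float = 0.25) -> list[Beat]:
    """Cut the pressure record into beats on half-open R-R windows.

    One beat per R-R interval; beats shorter than ``min_beat_s`` are discarded
    with a logged warning.
    """
    r = np.asarray(rec.r_peaks, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 R peaks to segment beats")
    w = rec.pressure
    beats: list[Beat] = []
    for t_a, t_b in zip(r[:-1], r[1:]):
        i_a = int(round((t_a - w.t0) * w.fs))
        i_b = int(round((t_b - w.t0) * w.fs))
        i_a, i_b = max(0, i_a), min(w.n, i_b)
        if (i_b - i_a) < min_beat_s * w.fs:
            logger.warning("discarding beat at t=%.3f s: shorter than %.2f s", t_a, min_beat_s)
            continue
        beats.append(Beat(w.samples[i_a:i_b], fs=w.fs, onset_time=w.t0 + i_a / w.fs))
    return beats
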