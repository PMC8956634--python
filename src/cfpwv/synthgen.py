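"""Synthetic two-site pressure records with known transit times.

A parametric aortic pressure template (raised-cosine systolic upstroke,
dicrotic bump, exponential diastolic decay) is propagated through a parallel
dual tube-load model to the carotid and femoral sites, so the true
aorta-carotid (``ac_td``) and aorta-femoral (``af_td``) transit times — and
hence the carotid-femoral transit time ``af_td - ac_td`` — are known exactly.

Realism knobs break the "fit model equals generating model" tautology:

* ``alpha`` adds per-harmonic viscous attenuation absent from the lossless
  fit model,
* terminal Windkessel loads add frequency-dependent reflections,
* R-R jitter and a between-session heart-rate offset emulate sequential
  (non-simultaneous) tonometric acquisition synchronized by ECG,
* :func:`degrade` applies gain, sinusoidal baseline drift, decimation to the
  128 Hz acquisition rate, and additive Gaussian noise at a stated SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signals import SiteRecording, Waveform, add_gaussian_noise, resample_linear
from .tubeload import TubeLoadParams, propagate_beat

__all__ = [
    "SubjectSpec",
    "SyntheticTruth",
    "aortic_template",
    "generate_record",
    "degrade",
    "generate_cohort",
    "DEFAULT_RANGES",
]

_FS_INTERNAL = 1000.0


@dataclass(frozen=True)
class SubjectSpec:
    """Generator settings for one synthetic subject.

    Transit times are the ground truth: ``cfPTT = af_td - ac_td`` by
    construction.  ``alpha`` is the dimensionless per-transit attenuation
    (model-mismatch control), ``hr_jitter_sd`` the beat-to-beat R-R standard
    deviation in seconds and ``hr_offset_sd`` the standard deviation (bpm) of
    the seeded mean-heart-rate difference between the two sequential
    sessions.
    """

    hr: float = 70.0
    sbp: float = 120.0
    dbp: float = 75.0
    ac_td: float = 0.02
    af_td: float = 0.10
    carotid_params: TubeLoadParams | None = None
    femoral_params: TubeLoadParams | None = None
    alpha: float = 0.05
    distance_cf: float = 0.6
    fs_record: float = 128.0
    duration: float = 30.0
    hr_jitter_sd: float = 0.02
    hr_offset_sd: float = 0.25

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError("need sbp > dbp > 0")
        if not (self.af_td > self.ac_td > 0):
            raise ValueError("need af_td > ac_td > 0")
        if self.hr <= 0 or self.duration <= 0 or self.fs_record <= 0:
            raise ValueError("hr, duration and fs_record must be positive")
        if self.carotid_params is None:
            object.__setattr__(
                self, "carotid_params", TubeLoadParams(self.ac_td, 0.2, 0.08)
            )
        if self.femoral_params is None:
            object.__setattr__(
                self, "femoral_params", TubeLoadParams(self.af_td, 0.2, 0.08)
            )
        if not math.isclose(self.carotid_params.td, self.ac_td):
            raise ValueError("carotid_params.td must equal ac_td")
        if not math.isclose(self.femoral_params.td, self.af_td):
            raise ValueError("femoral_params.td must equal af_td")

    @property
    def cf_ptt_true(self) -> float:
        return self.af_td - self.ac_td


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated subject, with the generator settings."""

    spec: SubjectSpec
    cf_ptt_true: float
    cf_pwv_true: float
    seed: int
    distance_factor: float = 0.8


def _template_period(period: float, fs: float, sbp: float, dbp: float) -> np.ndarray:
    """One period of the analytic aortic pressure contour.

    Raised-cosine upstroke (~100 ms), Gaussian dicrotic bump at ~35% of the
    cycle, exponential diastolic decay; continuous at the period boundary and
    affinely mapped so min = dbp and max = sbp.
    """
    n = max(2, int(round(period * fs)))
    T = n / fs
    t = np.arange(n) / fs
    ts = min(0.12, 0.25 * T)
    tau = T / 3.0
    tn = 0.35 * T
    sn = 0.04 * T
    amp_n = 0.12
    decay = np.exp(-(t - ts) / tau)
    bump = amp_n * np.exp(-0.5 * ((t - tn) / sn) ** 2)
    v_end = math.exp(-(T - ts) / tau) + amp_n * math.exp(-0.5 * ((T - tn) / sn) ** 2)
    upstroke = v_end + (1.0 - v_end) * 0.5 * (1.0 - np.cos(np.pi * t / ts))
    v = np.where(t < ts, upstroke, decay + bump)
    lo, hi = v.min(), v.max()
    return dbp + (v - lo) * (sbp - dbp) / (hi - lo)


def aortic_template(spec: SubjectSpec, fs: float = _FS_INTERNAL) -> Waveform:
    """One cardiac period of the aortic pressure waveform for ``spec``."""
    return Waveform(_template_period(60.0 / spec.hr, fs, spec.sbp, spec.dbp), fs=fs)


def _ecg_from_peaks(n: int, fs: float, peak_times: np.ndarray) -> np.ndarray:
    """Impulse-like synthetic ECG: a narrow Gaussian QRS at each R time."""
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    for tp in peak_times:
        ecg += np.exp(-0.5 * ((t - tp) / 0.008) ** 2)
    return ecg


def _session(
    spec: SubjectSpec,
    rr: np.ndarray,
    fs: float,
    sites: dict[str, tuple[TubeLoadParams | None, float]],
) -> dict[str, SiteRecording]:
    """Build synchronized recordings for one session from an R-R sequence.

    ``sites`` maps a site label to ``(params, alpha)``; ``params=None`` means
    the aortic input itself.
    """
    onsets = np.concatenate([[0.0], np.cumsum(np.round(rr * fs) / fs)])
    chunks: dict[str, list[np.ndarray]] = {s: [] for s in sites}
    for T in np.diff(onsets):
        beat = _template_period(T, fs, spec.sbp, spec.dbp)
        for site, (params, alpha) in sites.items():
            if params is None:
                chunks[site].append(beat)
            else:
                chunks[site].append(propagate_beat(beat, fs, params, alpha=alpha))
    total_n = int(round(onsets[-1] * fs))
    r_peaks = onsets[:-1]
    recs: dict[str, SiteRecording] = {}
    ecg_samples = _ecg_from_peaks(total_n, fs, r_peaks)
    for site in sites:
        samples = np.concatenate(chunks[site])[:total_n]
        pressure = Waveform(samples, fs=fs, t0=0.0)
        ecg = Waveform(ecg_samples, fs=fs, t0=0.0)
        recs[site] = SiteRecording(pressure=pressure, ecg=ecg, r_peaks=r_peaks, site=site)
    return recs


def generate_record(
    spec: SubjectSpec,
    seed: int,
    mode: str = "sequential",
    fs: float = _FS_INTERNAL,
) -> tuple[SiteRecording, SiteRecording, SiteRecording, SyntheticTruth]:
    """Generate clean 1 kHz aortic/carotid/femoral recordings plus the truth.

    ``mode="simultaneous"`` shares one R-R sequence across all three sites
    (the analogue of simulated numerical data); ``mode="sequential"`` builds
    two sessions — carotid and femoral — with independently jittered R-R
    sequences whose mean heart rates differ by a seeded draw, emulating
    sequential tonometric acquisition.  Deterministic given ``seed``.
    """
    if mode not in ("sequential", "simultaneous"):
        raise ValueError("mode must be 'sequential' or 'simultaneous'")
    ss = np.random.SeedSequence(seed)
    rng_c, rng_f, rng_off = (np.random.default_rng(s) for s in ss.spawn(3))
    n_beats = max(2, int(round(spec.duration / (60.0 / spec.hr)))) + 1

    def rr_seq(rng: np.random.Generator, hr: float) -> np.ndarray:
        base = 60.0 / hr
        rr = base + rng.normal(0.0, spec.hr_jitter_sd, n_beats)
        return np.clip(rr, 0.3, None)

    if mode == "simultaneous":
        rr = rr_seq(rng_c, spec.hr)
        recs = _session(
            spec,
            rr,
            fs,
            {
                "aortic": (None, 0.0),
                "carotid": (spec.carotid_params, spec.alpha),
                "femoral": (spec.femoral_params, spec.alpha),
            },
        )
        aortic, carotid, femoral = recs["aortic"], recs["carotid"], recs["femoral"]
    else:
        hr_offset = float(rng_off.normal(0.0, spec.hr_offset_sd)) if spec.hr_offset_sd else 0.0
        rr_c = rr_seq(rng_c, spec.hr)
        rr_f = rr_seq(rng_f, spec.hr + hr_offset)
        sess_c = _session(
            spec, rr_c, fs,
            {"aortic": (None, 0.0), "carotid": (spec.carotid_params, spec.alpha)},
        )
        sess_f = _session(
            spec, rr_f, fs,
            {"femoral": (spec.femoral_params, spec.alpha)},
        )
        aortic, carotid, femoral = sess_c["aortic"], sess_c["carotid"], sess_f["femoral"]
    truth = SyntheticTruth(
        spec=spec,
        cf_ptt_true=spec.cf_ptt_true,
        cf_pwv_true=0.8 * spec.distance_cf / spec.cf_ptt_true,
        seed=int(seed),
    )
    return aortic, carotid, femoral, truth


def degrade(
    rec: SiteRecording,
    snr_db: float = np.inf,
    drift_amp: float = 0.0,
    drift_hz: float = 0.2,
    gain: float = 1.0,
    seed: int = 0,
    fs_out: float | None = None,
) -> SiteRecording:
    """Measurement-chain emulation: gain, drift, decimation, noise.

    Applies (in order) an amplitude gain, additive sinusoidal baseline drift,
    anti-aliased decimation to ``fs_out`` (moving-average then linear
    sampling), and seeded Gaussian noise at ``snr_db`` on the pressure
    channel.  The ECG channel is decimated only; R-peak times are unchanged.
    With no noise, drift, unit gain and unchanged rate this is the identity.
    """
    w = rec.pressure
    samples = w.samples
    if gain != 1.0:
        samples = gain * samples
    if drift_amp:
        samples = samples + drift_amp * np.sin(2.0 * np.pi * drift_hz * w.times)
    pressure = w.with_samples(samples) if samples is not w.samples else w
    ecg = rec.ecg
    if fs_out is not None and not math.isclose(fs_out, w.fs):
        ratio = int(round(w.fs / fs_out))
        if ratio > 1:
            kernel = np.ones(ratio) / ratio
            smoothed = np.convolve(pressure.samples, kernel, mode="same")
            pressure = pressure.with_samples(smoothed)
        pressure = resample_linear(pressure, fs_out)
        if ecg is not None:
            ecg = resample_linear(ecg, fs_out)
    if not np.isinf(snr_db):
        pressure = add_gaussian_noise(pressure, snr_db, seed)
    r = rec.r_peaks
    if r.size and pressure.duration < (r[-1] - pressure.t0):
        r = r[r <= pressure.t0 + pressure.duration + 0.5 / pressure.fs]
    if ecg is not None and abs(ecg.duration - pressure.duration) > 1.0 / pressure.fs:
        ecg = Waveform(
            np.interp(
                pressure.t0 + np.arange(pressure.n) / pressure.fs,
                ecg.times,
                ecg.samples,
            ),
            fs=pressure.fs,
            t0=pressure.t0,
        )
    return SiteRecording(pressure=pressure, ecg=ecg, r_peaks=r, site=rec.site)


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "hr": (55.0, 85.0),
    "sbp": (105.0, 135.0),
    "dbp": (62.0, 82.0),
    "ac_td": (0.015, 0.03),
    "cf_pwv": (5.0, 12.0),
    "distance_cf": (0.5, 0.7),
    "tau_rc": (0.1, 0.35),
    "tau_zc": (0.05, 0.1),
}


def _spec_from_draw(rng: np.random.Generator, ranges: dict, **overrides) -> SubjectSpec:
    u = {k: rng.uniform(*ranges[k]) for k in ("hr", "sbp", "dbp", "ac_td", "cf_pwv", "distance_cf")}
    cf_ptt = 0.8 * u["distance_cf"] / u["cf_pwv"]
    af_td = u["ac_td"] + cf_ptt
    taus = {s: (rng.uniform(*ranges["tau_rc"]), rng.uniform(*ranges["tau_zc"])) for s in "cf"}
    return SubjectSpec(
        hr=u["hr"],
        sbp=u["sbp"],
        dbp=u["dbp"],
        ac_td=u["ac_td"],
        af_td=af_td,
        carotid_params=TubeLoadParams(u["ac_td"], *taus["c"]),
        femoral_params=TubeLoadParams(af_td, *taus["f"]),
        distance_cf=u["distance_cf"],
        **overrides,
    )


def generate_cohort(
    n: int,
    ranges: dict | None = None,
    sweep: str | None = None,
    sweep_fraction: float = 0.2,
    step: float = 0.01,
    seed: int = 0,
    base_spec: SubjectSpec | None = None,
    **spec_overrides,
) -> list[SyntheticTruth]:
    """Draw a cohort of synthetic subjects, or sweep one parameter.

    Random mode (``sweep=None``): ``n`` subjects with parameters drawn from
    ``ranges`` (defaults: :data:`DEFAULT_RANGES`; true cfPWV uniform over a
    physiologic 5-12 m/s).  Sweep mode: the named parameter (e.g.
    ``"af_td"``) of ``base_spec`` is varied deterministically in ``step``
    fractional increments over ``+-sweep_fraction`` (the default +-20% in 1%
    steps yields 41 subjects, ``n`` is ignored).  Deterministic given
    ``seed``.
    """
    if sweep is None and n < 1:
        raise ValueError("n must be >= 1")
    eff = dict(DEFAULT_RANGES)
    if ranges:
        for k, v in ranges.items():
            if v is None or (hasattr(v, "__len__") and len(v) == 0):
                raise ValueError(f"empty range for {k!r}")
            eff[k] = v
    ss = np.random.SeedSequence(seed)
    truths: list[SyntheticTruth] = []
    if sweep is not None:
        base = base_spec or SubjectSpec(**spec_overrides)
        k = int(round(sweep_fraction / step))
        factors = 1.0 + step * np.arange(-k, k + 1)
        for j, f in enumerate(factors):
            value = getattr(base, sweep) * f
            changes: dict = {sweep: value}
            # keep the dependent tube parameter triples consistent
            if sweep == "ac_td":
                changes["carotid_params"] = replace(base.carotid_params, td=value)
            if sweep == "af_td":
                changes["femoral_params"] = replace(base.femoral_params, td=value)
            spec = replace(base, **changes)
            sub_seed = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31))
            truths.append(
                SyntheticTruth(
                    spec=spec,
                    cf_ptt_true=spec.cf_ptt_true,
                    cf_pwv_true=0.8 * spec.distance_cf / spec.cf_ptt_true,
                    seed=sub_seed,
                )
            )
        return truths
    children = ss.spawn(n)
    for child in children:
        rng = np.random.default_rng(child)
        spec = _spec_from_draw(rng, eff, **spec_overrides)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        truths.append(
            SyntheticTruth(
                spec=spec,
                cf_ptt_true=spec.cf_ptt_true,
                cf_pwv_true=0.8 * spec.distance_cf / spec.cf_ptt_true,
                seed=sub_seed,
            )
        )
    return truths
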