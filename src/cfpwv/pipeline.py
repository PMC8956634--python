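"""End-to-end preprocessing and estimation pipeline.

Mirrors the measurement protocol: baseline-drift removal, up-sampling to
1 kHz by linear interpolation, R-peak synchronization of the sequential
carotid and femoral recordings (with the 1 bpm heart-rate matching rule),
per-beat transit-time estimation, per-beat averaging, and conversion to PWV
with the 0.8 path-length correction.
"""

from __future__ import annotations

import numpy as np

from . import estimators
from .signals import (
    SiteRecording,
    check_hr_match,
    detect_r_peaks,
    mean_heart_rate,
    remove_baseline,
    resample_linear,
    segment_beats,
)

__all__ = ["preprocess_recording", "estimate_ptt", "HeartRateMismatch"]


class HeartRateMismatch(ValueError):
    """Mean heart rates of the two sessions differ by more than the rule allows."""


def preprocess_recording(
    rec: SiteRecording,
    fs_target: float = 1000.0,
    baseline_cutoff: float = 0.5,
) -> SiteRecording:
    """Baseline removal then linear-interpolation resampling to ``fs_target``."""
    pressure = remove_baseline(rec.pressure, cutoff_hz=baseline_cutoff)
    pressure = resample_linear(pressure, fs_target)
    ecg = resample_linear(rec.ecg, fs_target) if rec.ecg is not None else None
    r = np.asarray(rec.r_peaks, dtype=float)
    if r.size == 0 and ecg is not None:
        r = detect_r_peaks(ecg)
    if r.size and r[-1] > pressure.t0 + pressure.duration:
        r = r[r <= pressure.t0 + pressure.duration + 0.5 / pressure.fs]
    return SiteRecording(pressure=pressure, ecg=ecg, r_peaks=r, site=rec.site)


def _common_beats(*recs: SiteRecording):
    """Segment each recording and truncate to the common beat count."""
    seqs = [segment_beats(r) for r in recs]
    m = min(len(s) for s in seqs)
    if m == 0:
        raise ValueError("no complete beats in one of the recordings")
    return [s[:m] for s in seqs]


def estimate_ptt(
    carotid: SiteRecording,
    femoral: SiteRecording,
    method: str = "tubeload",
    aortic: SiteRecording | None = None,
    hr_tol_bpm: float = 1.0,
    enforce_hr_rule: bool = False,
    preprocess: bool = False,
    **estimator_kwargs,
):
    """Fit one transit-time estimator on a carotid/femoral recording pair.

    Set ``preprocess=True`` to run :func:`preprocess_recording` first (raw
    128 Hz records); ``enforce_hr_rule=True`` applies the 1 bpm sequential
    validity rule and raises :class:`HeartRateMismatch` on failure.  Returns
    the fitted estimator (``.ptt_``, ``.per_beat_ptt_``, ``.pwv(...)``).
    """
    if preprocess:
        carotid = preprocess_recording(carotid)
        femoral = preprocess_recording(femoral)
        if aortic is not None:
            aortic = preprocess_recording(aortic)
    if enforce_hr_rule:
        hr_c = mean_heart_rate(carotid.r_peaks)
        hr_f = mean_heart_rate(femoral.r_peaks)
        if not check_hr_match(hr_c, hr_f, tol=hr_tol_bpm):
            raise HeartRateMismatch(
                f"mean heart rates differ by {abs(hr_c - hr_f):.2f} bpm "
                f"(> {hr_tol_bpm} bpm rule); carotid {hr_c:.1f}, femoral {hr_f:.1f}"
            )
    est = estimators.make_estimator(method, **estimator_kwargs)
    if method == "xcorr":
        return est.fit(carotid, femoral)
    if method == "dualtube":
        if aortic is None:
            raise ValueError("dualtube requires an aortic recording")
        a, c, f = _common_beats(aortic, carotid, femoral)
        return est.fit(a, c, f)
    c, f = _common_beats(carotid, femoral)
    return est.fit(c, f)
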