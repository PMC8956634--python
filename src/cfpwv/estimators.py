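"""Scikit-learn-style transit-time estimators.

Each estimator is fit on a proximal/distal pair of recordings (or beat
sequences) and exposes the fitted transit time through trailing-underscore
attributes::

    est = TubeLoadPTT().fit(carotid, femoral)
    est.ptt_            # mean transit time, s
    est.per_beat_ptt_   # per-beat values, s
    est.pwv(0.6)        # m/s, with the 0.8 path-length correction

All estimators derive from :class:`sklearn.base.BaseEstimator`, so
``get_params`` / ``set_params`` (and hence grid search over e.g. the
cross-correlation window fraction) work as usual.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import fiducial, tubeload
from .fiducial import PTTResult
from .signals import Beat, SiteRecording, Waveform, segment_beats

__all__ = [
    "IntersectingTangentPTT",
    "WaveformMatchingPTT",
    "CrossCorrelationPTT",
    "TubeLoadPTT",
    "DualTubePTT",
    "METHODS",
    "make_estimator",
]


def _as_beats(x) -> list[Beat]:
    if isinstance(x, SiteRecording):
        return segment_beats(x)
    if isinstance(x, Beat):
        return [x]
    beats = list(x)
    if not all(isinstance(b, Beat) for b in beats):
        raise TypeError("expected a SiteRecording or a sequence of Beats")
    return beats


def _paired_beats(prox, dist) -> list[tuple[Beat, Beat]]:
    pb, db = _as_beats(prox), _as_beats(dist)
    if len(pb) != len(db):
        extra = range(min(len(pb), len(db)), max(len(pb), len(db)))
        raise ValueError(
            f"unpaired beats at indices {list(extra)}: "
            f"{len(pb)} proximal vs {len(db)} distal"
        )
    if not pb:
        raise ValueError("no beats to pair")
    return list(zip(pb, db))


class _BasePTT(BaseEstimator):
    """Shared plumbing: fitted attributes, PWV derivation, result assembly."""

    method_name: str = ""

    def _finalize(self, per_beat: np.ndarray) -> "._BasePTT":
        per_beat = np.asarray(per_beat, dtype=float)
        self.per_beat_ptt_ = per_beat
        self.ptt_ = float(np.mean(per_beat))
        self.n_beats_ = int(per_beat.size)
        self.result_ = PTTResult(
            method=self.method_name,
            per_beat_ptt=per_beat,
            ptt_mean=self.ptt_,
            n_beats=self.n_beats_,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "ptt_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted yet")

    def pwv(self, distance_m: float, factor: float = 0.8) -> float:
        """Pulse wave velocity (m/s) from the fitted mean transit time."""
        self._check_fitted()
        return tubeload.pwv_from_ptt(distance_m, self.ptt_, factor=factor)


class IntersectingTangentPTT(_BasePTT):
    """Foot-to-foot transit time from the intersecting-tangent fiducial point.

    For each R-aligned beat pair the foot (tangent at the maximum systolic
    slope crossed with the horizontal through the diastolic minimum) is
    located in both waveforms; the per-beat transit time is the difference of
    the foot times relative to each beat's R peak, and the reported PTT is
    their mean.

    Parameters
    ----------
    smooth_ms : float
        Moving-average width applied before differentiation (0 disables).
    search_frac : float
        Fraction of the beat searched for the diastolic minimum.
    """

    method_name = "tangent"

    def __init__(self, smooth_ms: float = 25.0, search_frac: float = 0.4):
        self.smooth_ms = smooth_ms
        self.search_frac = search_frac

    def fit(self, prox, dist):
        pairs = _paired_beats(prox, dist)
        ptts = []
        for bp, bd in pairs:
            fp = fiducial.foot_intersecting_tangent(
                bp, smooth_ms=self.smooth_ms, search_frac=self.search_frac
            )
            fd = fiducial.foot_intersecting_tangent(
                bd, smooth_ms=self.smooth_ms, search_frac=self.search_frac
            )
            ptts.append((fd - bd.onset_time) - (fp - bp.onset_time))
        return self._finalize(np.asarray(ptts))


class WaveformMatchingPTT(_BasePTT):
    """Diastolic-patch waveform-matching transit time.

    A min-max-normalized patch centred on the proximal diastolic minimum
    (half-width: diastolic minimum to maximum first derivative) is slid over
    the distal beat in 1-sample steps; the SSE-optimal shift is the per-beat
    transit time.
    """

    method_name = "match"

    def __init__(
        self,
        shift_max_s: float = 0.3,
        smooth_ms: float = 25.0,
        search_frac: float = 0.4,
    ):
        self.shift_max_s = shift_max_s
        self.smooth_ms = smooth_ms
        self.search_frac = search_frac

    def fit(self, prox, dist):
        pairs = _paired_beats(prox, dist)
        ptts = []
        sses = []
        for bp, bd in pairs:
            s, sse = fiducial.matching_shift(
                bp,
                bd,
                shift_max_s=self.shift_max_s,
                smooth_ms=self.smooth_ms,
                search_frac=self.search_frac,
            )
            ptts.append(s)
            sses.append(sse)
        self.per_beat_sse_ = np.asarray(sses)
        return self._finalize(np.asarray(ptts))


class CrossCorrelationPTT(_BasePTT):
    """Transit time from the correlation peak of two multi-beat windows.

    Operates on the full records (middle ``window_fraction``), not per beat.
    Sequential recordings are first synchronized one beat at a time on their
    ECG R peaks (the distal record is re-gated onto the proximal R grid), so
    cumulative R-R drift between the two sessions does not masquerade as
    transit time; plain waveforms are assumed already time-aligned.
    """

    method_name = "xcorr"

    def __init__(self, window_fraction: float = 0.8, shift_max_s: float = 0.3):
        self.window_fraction = window_fraction
        self.shift_max_s = shift_max_s

    @staticmethod
    def _regate(prox: SiteRecording, dist: SiteRecording) -> tuple[Waveform, Waveform]:
        """Concatenate R-aligned beat pairs onto one common grid."""
        pb, db = segment_beats(prox), segment_beats(dist)
        m = min(len(pb), len(db))
        if m == 0:
            raise ValueError("no complete beats to synchronize")
        p_chunks, d_chunks = [], []
        for bp, bd in zip(pb[:m], db[:m]):
            L = bp.n
            d = bd.samples
            if d.size >= L:
                d = d[:L]
            else:
                d = np.concatenate([d, np.full(L - d.size, d[-1])])
            p_chunks.append(bp.samples)
            d_chunks.append(d)
        fs = pb[0].fs
        return (
            Waveform(np.concatenate(p_chunks), fs=fs, t0=0.0),
            Waveform(np.concatenate(d_chunks), fs=fs, t0=0.0),
        )

    def fit(self, prox, dist):
        if (
            isinstance(prox, SiteRecording)
            and isinstance(dist, SiteRecording)
            and len(prox.r_peaks) >= 2
            and len(dist.r_peaks) >= 2
        ):
            wp, wd = self._regate(prox, dist)
        else:
            wp = prox if isinstance(prox, Waveform) else prox.pressure
            wd = dist if isinstance(dist, Waveform) else dist.pressure
        s, r = fiducial.xcorr_shift(
            wp, wd, window_fraction=self.window_fraction, shift_max_s=self.shift_max_s
        )
        self.peak_coefficient_ = r
        return self._finalize(np.asarray([s]))


class TubeLoadPTT(_BasePTT):
    """Single-tube tube-load transit time (the model-based method).

    Each R-aligned beat pair is fit with the lossless-tube + Windkessel
    transfer function by globally initialized bounded nonlinear least
    squares; the per-beat transit time is the fitted model parameter ``T_d``
    and the reported PTT is the per-beat average.  ``T_d`` is continuous in
    the model phase term, so sub-sample resolution is possible.

    Parameters
    ----------
    bounds : FitBounds or None
        Box constraints on ``(T_d, tau_rc, tau_zc)``.
    grid : MultistartGrid or None
        Coarse initialization grid for the global search.
    seed : int or None
        Reserved; the multistart grid is deterministic.
    """

    method_name = "tubeload"

    def __init__(self, bounds=None, grid=None, seed=None):
        self.bounds = bounds
        self.grid = grid
        self.seed = seed

    def fit(self, prox, dist):
        import logging

        pairs = _paired_beats(prox, dist)
        bounds = self.bounds or tubeload.FitBounds()
        grid = self.grid or tubeload.MultistartGrid()
        per_beat, rss, conv, pinned = [], [], [], []
        for bp, bd in pairs:
            if not np.isclose(bp.fs, bd.fs):
                raise ValueError("beats must share sampling rate")
            params, r, c, pin = tubeload.fit_beat_pair(
                bp.samples, bd.samples, bp.fs, bounds=bounds, grid=grid
            )
            per_beat.append(params)
            rss.append(r)
            conv.append(c)
            pinned.append(pin)
        if not any(conv):
            raise RuntimeError("tube-load fit: no beat converged")
        if any(pinned):
            logging.getLogger(__name__).warning(
                "tube-load fit: T_d pinned at a bound in %d/%d beats",
                sum(pinned),
                len(pinned),
            )
        self.per_beat_params_ = per_beat
        self.per_beat_rss_ = np.asarray(rss)
        self.converged_ = bool(all(conv))
        self.boundary_pinned_ = bool(any(pinned))
        mean_params = _mean_params(per_beat)
        self.fit_result_ = tubeload.FitResult(
            params=mean_params,
            rss=float(np.sum(rss)),
            n_restarts=len(grid.points()),
            converged=self.converged_,
            per_beat=per_beat,
            per_beat_rss=self.per_beat_rss_,
            boundary_pinned=self.boundary_pinned_,
        )
        return self._finalize(np.asarray([p.td for p in per_beat]))

    def diagnostics_frame(self):
        """Per-beat fit diagnostics as a DataFrame (exportable as CSV)."""
        import pandas as pd

        self._check_fitted()
        return pd.DataFrame(
            {
                "td": [p.td for p in self.per_beat_params_],
                "tau_rc": [p.tau_rc for p in self.per_beat_params_],
                "tau_zc": [p.tau_zc for p in self.per_beat_params_],
                "rss": self.per_beat_rss_,
                "converged": self.converged_,
            }
        )


def _mean_params(per_beat) -> tubeload.TubeLoadParams:
    """Average the per-beat parameter triples into one representative set."""
    return tubeload.TubeLoadParams(
        td=float(np.mean([p.td for p in per_beat])),
        tau_rc=float(np.mean([p.tau_rc for p in per_beat])),
        tau_zc=float(np.mean([p.tau_zc for p in per_beat])),
    )


class DualTubePTT(_BasePTT):
    """Parallel dual-tube transit time: ``cfPTT = |afPTT - acPTT|``.

    Two independent single-tube fits share the aortic waveform as input: one
    to the carotid (acPTT) and one to the femoral (afPTT) site; their
    absolute difference is the carotid-femoral transit time.
    """

    method_name = "dualtube"

    def __init__(self, bounds=None, grid=None, seed=None):
        self.bounds = bounds
        self.grid = grid
        self.seed = seed

    def fit(self, aortic, carotid, femoral):
        try:
            ac = TubeLoadPTT(bounds=self.bounds, grid=self.grid).fit(aortic, carotid)
        except Exception as exc:
            raise RuntimeError(f"aorta-carotid tube fit failed: {exc}") from exc
        try:
            af = TubeLoadPTT(bounds=self.bounds, grid=self.grid).fit(aortic, femoral)
        except Exception as exc:
            raise RuntimeError(f"aorta-femoral tube fit failed: {exc}") from exc
        self.ac_ptt_ = ac.ptt_
        self.af_ptt_ = af.ptt_
        self.ac_fit_ = ac
        self.af_fit_ = af
        per_beat = np.abs(af.per_beat_ptt_ - ac.per_beat_ptt_)
        self._finalize(per_beat)
        # the headline PTT is |mean afPTT - mean acPTT|
        self.ptt_ = float(abs(self.af_ptt_ - self.ac_ptt_))
        self.result_ = PTTResult(
            method=self.method_name,
            per_beat_ptt=per_beat,
            ptt_mean=float(np.mean(per_beat)),
            n_beats=per_beat.size,
        )
        return self


METHODS: dict[str, type] = {
    "tangent": IntersectingTangentPTT,
    "match": WaveformMatchingPTT,
    "xcorr": CrossCorrelationPTT,
    "tubeload": TubeLoadPTT,
    "dualtube": DualTubePTT,
}


def make_estimator(method: str, **kwargs):
    """Instantiate a PTT estimator by its CLI name."""
    try:
        cls = METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return cls(**kwargs)
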