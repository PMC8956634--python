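"""Fiducial-point transit-time primitives.

The three classical carotid-femoral transit-time estimators all reduce to a
small set of per-beat primitives:

* the *diastolic minimum* (the foot-region minimum of the pulse),
* the *maximum of the first derivative* during the systolic upstroke,
* the *intersecting-tangent foot* (tangent at the max-slope point crossed
  with the horizontal through the diastolic minimum),
* an SSE-optimal shift of a diastolic patch (*waveform matching*), and
* the shift maximizing the Pearson correlation of two multi-beat windows
  (*cross-correlation*).

The estimator classes in :mod:`cfpwv.estimators` orchestrate these primitives
over paired beat sequences; module-level ``ptt_*`` wrappers are provided for a
functional API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signals import Beat, Waveform

__all__ = [
    "PTTResult",
    "diastolic_minimum",
    "max_first_derivative",
    "foot_intersecting_tangent",
    "matching_shift",
    "xcorr_shift",
    "ptt_intersecting_tangent",
    "ptt_waveform_matching",
    "ptt_cross_correlation",
]


@dataclass(frozen=True)
class PTTResult:
    """Per-beat transit times and their mean for one method."""

    method: str
    per_beat_ptt: np.ndarray
    ptt_mean: float
    n_beats: int
    pwv: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.per_beat_ptt, dtype=float)
        object.__setattr__(self, "per_beat_ptt", p)
        if p.size != self.n_beats:
            raise ValueError("n_beats must equal len(per_beat_ptt)")
        if p.size and not np.isclose(self.ptt_mean, float(np.mean(p))):
            raise ValueError("ptt_mean must be the arithmetic mean of per_beat_ptt")


def _smoothed(samples: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    """Moving-average smoother; ``smooth_ms = 0`` disables it."""
    win = int(round(smooth_ms * 1e-3 * fs))
    if win < 2:
        return samples
    kernel = np.ones(win) / win
    # reflect-pad so edges are not biased toward zero
    pad = win // 2
    ext = np.concatenate([samples[pad:0:-1], samples, samples[-2 : -pad - 2 : -1]])
    out = np.convolve(ext, kernel, mode="same")[pad : pad + samples.size]
    return out


def diastolic_minimum(b: Beat, search_frac: float = 0.4) -> float:
    """Time of the beat's diastolic minimum (the foot region).

    The search is confined to the first ``search_frac`` of the beat so the
    end-diastolic minimum of the *next* cycle is never picked up.  Ties go to
    the first occurrence.
    """
    n_search = max(2, int(np.ceil(search_frac * b.n)))
    window = b.samples[:n_search]
    if np.ptp(b.samples) == 0:
        raise ValueError("flat beat: no diastolic minimum")
    idx = int(np.argmin(window))
    return b.onset_time + idx / b.fs


def max_first_derivative(b: Beat, smooth_ms: float = 25.0, search_frac: float = 0.4) -> float:
    """Time of the maximum first derivative during the systolic upstroke.

    The derivative is a central difference of the (optionally 25 ms
    moving-average smoothed) beat, searched between the diastolic minimum and
    the beat maximum.  Ties go to the first sample.
    """
    t_min = diastolic_minimum(b, search_frac=search_frac)
    i_min = int(round((t_min - b.onset_time) * b.fs))
    y = _smoothed(b.samples, b.fs, smooth_ms)
    i_max = int(np.argmax(y))
    if i_max <= i_min:
        raise ValueError("no upstroke: beat maximum precedes the diastolic minimum")
    deriv = np.gradient(y) * b.fs
    seg = deriv[i_min : i_max + 1]
    idx = i_min + int(np.argmax(seg))
    return b.onset_time + idx / b.fs


def foot_intersecting_tangent(
    b: Beat, smooth_ms: float = 25.0, search_frac: float = 0.4
) -> float:
    """Intersecting-tangent foot of the pulse wave.

    The tangent to the waveform at the point of maximum systolic slope is
    intersected with the horizontal line through the diastolic minimum; the
    crossing time is the notional foot.  Invariant to vertical offset.
    """
    t_min = diastolic_minimum(b, search_frac=search_frac)
    t_slope = max_first_derivative(b, smooth_ms=smooth_ms, search_frac=search_frac)
    y = _smoothed(b.samples, b.fs, smooth_ms)
    i_min = int(round((t_min - b.onset_time) * b.fs))
    i_m = int(round((t_slope - b.onset_time) * b.fs))
    deriv = np.gradient(y) * b.fs
    slope = float(deriv[i_m])
    if slope <= 0:
        raise ValueError("no upstroke: non-positive tangent slope")
    p_min = float(y[i_min])
    p_m = float(y[i_m])
    return t_slope - (p_m - p_min) / slope


def _minmax(x: np.ndarray) -> np.ndarray:
    r = np.ptp(x)
    if r == 0:
        raise ValueError("zero-range segment cannot be normalized")
    return (x - x.min()) / r


def matching_shift(
    prox: Beat,
    dist: Beat,
    shift_max_s: float = 0.3,
    smooth_ms: float = 25.0,
    search_frac: float = 0.4,
) -> tuple[float, float]:
    """Waveform-matching (diastolic patch) transit time for one beat pair.

    A patch of half-width ``t`` (diastolic minimum to max first derivative)
    centred on the proximal diastolic minimum is min-max normalized and slid
    in 1-sample steps over the distal beat; the shift minimizing the SSE
    against the equally normalized distal segment is the transit time.

    Beats are treated as one period of a periodic signal (as everywhere in
    this package), so a patch extending before the beat onset — which always
    happens when the distal foot sits early in the R-R window — wraps to the
    end of the beat, and shifted distal segments wrap likewise.

    Returns ``(shift_seconds, sse_at_optimum)``.  Ties go to the smallest
    shift.
    """
    if not np.isclose(prox.fs, dist.fs):
        raise ValueError("beats must share sampling rate")
    fs = prox.fs
    t_min = diastolic_minimum(prox, search_frac=search_frac)
    t_sl = max_first_derivative(prox, smooth_ms=smooth_ms, search_frac=search_frac)
    i_min = int(round((t_min - prox.onset_time) * fs))
    half = int(round((t_sl - t_min) * fs))
    if half < 1:
        raise ValueError("degenerate patch: zero half-width")
    lo, hi = i_min - half, i_min + half + 1
    width = hi - lo
    if width > prox.n or width > dist.n:
        raise ValueError("patch exceeds beat bounds")
    patch = _minmax(prox.samples.take(range(lo, hi), mode="wrap"))
    max_shift = int(round(shift_max_s * fs))
    n_shifts = max_shift + 1
    idx = (lo + np.arange(n_shifts)[:, None] + np.arange(width)[None, :]) % dist.n
    segs = dist.samples[idx]
    rng_seg = segs.max(axis=1) - segs.min(axis=1)
    ok = rng_seg > 0
    if not np.any(ok):
        raise ValueError("zero-range distal segments")
    norm = (segs - segs.min(axis=1, keepdims=True)) / np.where(ok, rng_seg, 1.0)[:, None]
    sse = np.sum((norm - patch[None, :]) ** 2, axis=1)
    sse[~ok] = np.inf
    s = int(np.argmin(sse))
    return s / fs, float(sse[s])


def xcorr_shift(
    prox: Waveform,
    dist: Waveform,
    window_fraction: float = 0.8,
    shift_max_s: float = 0.3,
) -> tuple[float, float]:
    """Cross-correlation transit time over multi-beat windows.

    The middle ``window_fraction`` of the proximal record is correlated
    (Pearson) against the distal record shifted forward in 1-sample steps up
    to ``shift_max_s``; the shift maximizing the correlation coefficient is
    the transit time.  Both signals must share ``fs`` and be time-aligned.

    Returns ``(shift_seconds, peak_coefficient)``.  Ties go to the smallest
    shift.
    """
    if not np.isclose(prox.fs, dist.fs):
        raise ValueError("signals must share sampling rate")
    fs = prox.fs
    n = prox.n
    start = int(round((1.0 - window_fraction) / 2.0 * n))
    length = int(round(window_fraction * n))
    length = min(length, n - start)
    w = prox.samples[start : start + length]
    wc = w - w.mean()
    nw = float(np.dot(wc, wc))
    if nw == 0:
        raise ValueError("zero-variance proximal window")
    max_shift = int(round(shift_max_s * fs))
    last_start = dist.n - length
    if last_start < start:
        raise ValueError("distal record too short for the correlation window")
    n_shifts = min(max_shift, last_start - start) + 1
    if (length - max(0, start + n_shifts - 1 + length - dist.n)) < 0.5 * length:
        raise ValueError("overlap after max shift below 50% of window")
    segs = sliding_window_view(dist.samples, length)[start : start + n_shifts]
    seg_mean = segs.mean(axis=1)
    cross = segs @ wc  # wc has zero mean, so centering of segs cancels
    seg_ss = np.einsum("ij,ij->i", segs, segs) - length * seg_mean**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cross / np.sqrt(nw * seg_ss)
    r[~np.isfinite(r)] = -np.inf
    if not np.any(np.isfinite(r)):
        raise ValueError("zero-variance distal windows")
    s = int(np.argmax(r))
    return s / fs, float(r[s])


# ---------------------------------------------------------------------------
# functional wrappers over the estimator classes
# ---------------------------------------------------------------------------

def ptt_intersecting_tangent(prox, dist, **kwargs) -> PTTResult:
    """Foot-to-foot PTT via the intersecting tangent, per beat then averaged."""
    from .estimators import IntersectingTangentPTT

    return IntersectingTangentPTT(**kwargs).fit(prox, dist).result_


def ptt_waveform_matching(prox, dist, **kwargs) -> PTTResult:
    """Diastolic-patch waveform-matching PTT, per beat then averaged."""
    from .estimators import WaveformMatchingPTT

    return WaveformMatchingPTT(**kwargs).fit(prox, dist).result_


def ptt_cross_correlation(prox, dist, **kwargs) -> PTTResult:
    """Whole-record cross-correlation PTT."""
    from .estimators import CrossCorrelationPTT

    return CrossCorrelationPTT(**kwargs).fit(prox, dist).result_
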