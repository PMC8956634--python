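"""Lossless tube + three-element Windkessel transmission-line model.

The carotid-femoral path is modelled as a uniform lossless tube of transit
time ``T_d`` terminated by a three-element Windkessel (characteristic
impedance ``Zc`` in series with a parallel ``R``-``C`` bed).  Pressure
anywhere on the tube is a superposition of a forward wave and a wave
reflected at the termination with frequency-dependent reflection coefficient

    Gamma(w) = tau_rc / (tau_rc + 2 tau_zc + j w 2 tau_rc tau_zc),

where only the identifiable products ``tau_rc = R*C`` and ``tau_zc = Zc*C``
enter.  The proximal-to-distal pressure transfer function of the tube is

    H(w) = (1 + Gamma(w)) / (exp(j w T_d) + Gamma(w) exp(-j w T_d)),

which satisfies ``H(0) = 1`` identically and reduces to a pure delay
``exp(-j w T_d)`` for a matched termination (``tau_rc = 0``).  Estimating
``(T_d, tau_rc, tau_zc)`` by globally initialized bounded nonlinear least
squares on a measured proximal/distal beat pair yields the pulse transit
time directly as the model parameter ``T_d``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TubeGeometry",
    "WindkesselLoad",
    "TubeLoadParams",
    "TransferSpec",
    "FitBounds",
    "MultistartGrid",
    "FitResult",
    "characteristic_impedance",
    "propagation_time",
    "reflection_coefficient",
    "transfer_gain",
    "transfer_function",
    "propagate_beat",
    "predict_distal",
    "fit_beat_pair",
    "fit_single_tube",
    "fit_dual_tube",
    "pwv_from_ptt",
]


@dataclass(frozen=True)
class TubeGeometry:
    """Physical tube description: blood density, length, lumen area, compliance.

    Units: ``rho`` kg/m^3, ``L`` m, ``A`` m^2, ``C_tube`` m^3/Pa.
    """

    rho: float
    L: float
    A: float
    C_tube: float

    def __post_init__(self) -> None:
        for name in ("rho", "L", "A", "C_tube"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class WindkesselLoad:
    """Three-element terminal load: Zc in series with parallel R and C."""

    Zc: float
    R: float
    C_load: float

    def __post_init__(self) -> None:
        for name in ("Zc", "R", "C_load"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TubeLoadParams:
    """The identifiable parameter triple of one tube + load.

    ``td`` is the tube transit time (s); ``tau_rc = R*C`` and
    ``tau_zc = Zc*C`` are the load time constants (s).  ``tau_rc = 0``
    describes a matched (reflectionless) termination.
    """

    td: float
    tau_rc: float
    tau_zc: float

    def __post_init__(self) -> None:
        if self.td <= 0:
            raise ValueError("td must be > 0")
        if self.tau_rc < 0:
            raise ValueError("tau_rc must be >= 0")
        if self.tau_zc <= 0:
            raise ValueError("tau_zc must be > 0")


@dataclass(frozen=True)
class TransferSpec:
    """Transfer function and reflection coefficient on a frequency grid."""

    omega: np.ndarray
    H: np.ndarray
    gamma: np.ndarray


@dataclass(frozen=True)
class FitBounds:
    """Physiological box constraints for the nonlinear least-squares fit."""

    td: tuple[float, float] = (0.005, 0.3)
    tau_rc: tuple[float, float] = (0.0, 3.0)
    tau_zc: tuple[float, float] = (0.001, 0.1)

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.td[0], self.tau_rc[0], self.tau_zc[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.td[1], self.tau_rc[1], self.tau_zc[1]])


@dataclass(frozen=True)
class MultistartGrid:
    """Coarse initialization grid for the global parameter search."""

    td: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.151, 0.01), 3))
    tau_rc: tuple[float, ...] = (0.3, 1.0, 2.0)
    tau_zc: tuple[float, ...] = (0.005, 0.02, 0.05)
    n_refine: int = 1  # how many best starts are refined locally

    def points(self) -> np.ndarray:
        """All grid points, ordered by ascending td so rss ties break small."""
        pts = [
            (td, rc, zc)
            for td in sorted(self.td)
            for rc in self.tau_rc
            for zc in self.tau_zc
        ]
        return np.asarray(pts)


@dataclass
class FitResult:
    """Outcome of a single- or multi-beat tube-load fit."""

    params: TubeLoadParams
    rss: float
    n_restarts: int
    converged: bool
    per_beat: list[TubeLoadParams] | None = None
    per_beat_rss: np.ndarray | None = None
    boundary_pinned: bool = False


# ---------------------------------------------------------------------------
# model algebra
# ---------------------------------------------------------------------------

def characteristic_impedance(g: TubeGeometry) -> float:
    """``Zc = sqrt(rho L / (A C_tube))`` for a lossless uniform tube."""
    return math.sqrt(g.rho * g.L / (g.A * g.C_tube))


def propagation_time(g: TubeGeometry) -> float:
    """``T = sqrt(rho L C_tube / A)``; note ``T = Zc * C_tube``."""
    return math.sqrt(g.rho * g.L * g.C_tube / g.A)


def reflection_coefficient(omega, p: TubeLoadParams):
    """Terminal reflection coefficient ``Gamma(omega)`` of the Windkessel load."""
    omega = np.asarray(omega, dtype=float)
    return p.tau_rc / (p.tau_rc + 2.0 * p.tau_zc + 1j * omega * 2.0 * p.tau_rc * p.tau_zc)


def transfer_gain(omega, p: TubeLoadParams) -> np.ndarray:
    """Complex proximal-to-distal pressure gain ``H(omega)`` of the tube."""
    omega = np.asarray(omega, dtype=float)
    g = reflection_coefficient(omega, p)
    e = np.exp(1j * omega * p.td)
    return (1.0 + g) / (e + g / e)


def transfer_function(omega_grid, p: TubeLoadParams) -> TransferSpec:
    """Evaluate ``H`` and ``Gamma`` on a grid that must include ``omega = 0``."""
    omega = np.asarray(omega_grid, dtype=float)
    if not np.any(omega == 0):
        raise ValueError("frequency grid must include omega = 0")
    return TransferSpec(omega=omega, H=transfer_gain(omega, p), gamma=reflection_coefficient(omega, p))


def propagate_beat(
    samples: np.ndarray, fs: float, p: TubeLoadParams, alpha: float = 0.0
) -> np.ndarray:
    """Apply the tube transfer function to one beat treated as one period.

    ``alpha`` adds per-transit viscous attenuation ``exp(-alpha w T_d)`` on
    each harmonic (a deliberate departure from the lossless model, used by
    the synthetic generator to create model mismatch).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=1.0 / fs)
    h = transfer_gain(omega, p)
    if alpha:
        h = h * np.exp(-alpha * omega * p.td)
    return np.fft.irfft(np.fft.rfft(x) * h, n)


def predict_distal(prox, p: TubeLoadParams):
    """Distal beat predicted from a proximal beat under the model.

    The beat is treated as one period of a periodic signal; the output mean
    equals the input mean because ``H(0) = 1``.
    """
    from .signals import Beat

    if prox.n < 0.25 * prox.fs:
        raise ValueError("beat too short (< 0.25 s)")
    return Beat(propagate_beat(prox.samples, prox.fs, p), fs=prox.fs, onset_time=prox.onset_time)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _normalize01(x: np.ndarray) -> np.ndarray:
    r = np.ptp(x)
    if r == 0:
        raise ValueError("flat beat cannot be normalized")
    return (x - x.min()) / r


def _affine_residual(model: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Residual after projecting out gain and offset.

    Tonometric amplitude is uncalibrated, so a scalar gain/offset between the
    predicted and observed distal beats carries no information; it is solved
    in closed form before squaring so the noiseless forward-then-fit residual
    is exactly zero at the true parameters.
    """
    mm = model.mean()
    dm = target.mean()
    mc = model - mm
    var = float(np.dot(mc, mc))
    if var == 0:
        a = 0.0
    else:
        a = float(np.dot(mc, target - dm)) / var
    b = dm - a * mm
    return a * model + b - target


def fit_beat_pair(
    prox_samples: np.ndarray,
    dist_samples: np.ndarray,
    fs: float,
    bounds: FitBounds | None = None,
    grid: MultistartGrid | None = None,
    f_max: float | None = 30.0,
) -> tuple[TubeLoadParams, float, bool, bool]:
    """Fit ``(T_d, tau_rc, tau_zc)`` to one proximal/distal beat pair.

    Both beats are min-max normalized and the time-domain sum of squares
    between the model-predicted and observed distal beats — with a scalar
    gain/offset solved in closed form, since tonometric amplitude is
    uncalibrated — is minimized by a coarse multistart grid followed by
    bounded trust-region least squares on the best starts.  The objective is
    evaluated on the beat's harmonics up to ``f_max`` (by Parseval this
    equals the time-domain SSE of the band-limited signals; arterial
    pressure carries no usable content above ~30 Hz, so the cap discards
    only out-of-band noise).  ``f_max=None`` keeps every harmonic.  Ties in
    residual go to the smallest ``T_d``.

    Returns ``(params, rss, converged, boundary_pinned)``.
    """
    bounds = bounds or FitBounds()
    grid = grid or MultistartGrid()
    n = min(len(prox_samples), len(dist_samples))
    p = _normalize01(np.asarray(prox_samples[:n], dtype=float))
    d = _normalize01(np.asarray(dist_samples[:n], dtype=float))
    n_half = n // 2
    K = n_half if f_max is None else max(3, min(n_half, int(f_max * n / fs)))
    # harmonic k = 1..K; k = 0 is absorbed exactly by the offset term
    Pk = np.fft.rfft(p)[1 : K + 1]
    Dk = np.fft.rfft(d)[1 : K + 1]
    omega = 2.0 * np.pi * np.arange(1, K + 1) * fs / n
    # weights giving Parseval equivalence with the time-domain SSE
    wk = np.full(K, 2.0 / n)
    if K == n_half and n % 2 == 0:
        wk[-1] = 1.0 / n
    sw = np.sqrt(wk)

    def model_spec(theta: np.ndarray) -> np.ndarray:
        g = theta[1] / (theta[1] + 2.0 * theta[2] + 1j * omega * 2.0 * theta[1] * theta[2])
        e = np.exp(1j * omega * theta[0])
        return Pk * (1.0 + g) / (e + g / e)

    def _gain_parts(theta: np.ndarray):
        td, rc, zc = theta
        q = rc + 2.0 * zc + 1j * omega * 2.0 * rc * zc
        g = rc / q
        e = np.exp(1j * omega * td)
        den = e + g / e
        h = (1.0 + g) / den
        return g, q, e, den, h

    def _gain_from_m(m: np.ndarray) -> float:
        den = float(np.sum(wk * (m.real**2 + m.imag**2)))
        if den <= 0:
            return 0.0
        return float(np.sum(wk * (m.real * Dk.real + m.imag * Dk.imag))) / den

    def resid(theta: np.ndarray) -> np.ndarray:
        m = model_spec(theta)
        r = (_gain_from_m(m) * m - Dk) * sw
        return np.concatenate([r.real, r.imag])

    def jac(theta: np.ndarray) -> np.ndarray:
        g, q, e, den, h = _gain_parts(theta)
        m = Pk * h
        # dH/dtheta via the closed forms of g(rc, zc) and the tube phase
        dg = np.empty((3, omega.size), dtype=complex)
        dg[0] = 0.0
        dg[1] = 2.0 * theta[2] / q**2
        dg[2] = -2.0 * theta[1] * (1.0 + 1j * omega * theta[1]) / q**2
        dh_dg = 1.0 / den - (1.0 + g) / (e * den**2)
        dh = dh_dg[None, :] * dg
        dh[0] = -(1.0 + g) * 1j * omega * (e - g / e) / den**2
        dm = Pk[None, :] * dh
        a_den = float(np.sum(wk * (m.real**2 + m.imag**2)))
        if a_den <= 0:
            return np.zeros((2 * omega.size, 3))
        a_num = float(np.sum(wk * (m.real * Dk.real + m.imag * Dk.imag)))
        a = a_num / a_den
        cols = []
        for j in range(3):
            dnum = float(np.sum(wk * (dm[j].real * Dk.real + dm[j].imag * Dk.imag)))
            dden = 2.0 * float(np.sum(wk * (dm[j].real * m.real + dm[j].imag * m.imag)))
            da = (dnum * a_den - a_num * dden) / a_den**2
            dr = (da * m + a * dm[j]) * sw
            cols.append(np.concatenate([dr.real, dr.imag]))
        return np.column_stack(cols)

    # --- vectorized coarse grid ------------------------------------------
    pts = grid.points()
    pts = pts[
        np.all(pts >= bounds.lower[None, :], axis=1)
        & np.all(pts <= bounds.upper[None, :], axis=1)
    ]
    if pts.size == 0:
        pts = ((bounds.lower + bounds.upper) / 2.0)[None, :]
    td_g, rc_g, zc_g = pts[:, 0:1], pts[:, 1:2], pts[:, 2:3]
    g = rc_g / (rc_g + 2.0 * zc_g + 1j * omega[None, :] * 2.0 * rc_g * zc_g)
    e = np.exp(1j * omega[None, :] * td_g)
    M = Pk[None, :] * (1.0 + g) / (e + g / e)
    var = np.sum(wk[None, :] * (M.real**2 + M.imag**2), axis=1)
    cov = np.sum(wk[None, :] * (M.real * Dk.real[None, :] + M.imag * Dk.imag[None, :]), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    # rss without materializing residuals: ||D||^2_w - a^2 * var
    d_ss = float(np.sum(wk * (Dk.real**2 + Dk.imag**2)))
    rss_grid = d_ss - a**2 * var

    order = np.argsort(rss_grid, kind="stable")
    n_refine = max(1, grid.n_refine)
    best_params = None
    best_rss = np.inf
    converged = False
    for idx in order[:n_refine]:
        x0 = np.clip(pts[idx], bounds.lower, bounds.upper)
        try:
            sol = least_squares(
                resid,
                x0,
                jac=jac,
                bounds=(bounds.lower, bounds.upper),
                method="trf",
                x_scale=[0.05, 1.0, 0.02],
                xtol=1e-6,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=60,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        rss = float(2.0 * sol.cost)
        better = rss < best_rss * (1.0 - 1e-12) - 1e-300
        tie = abs(rss - best_rss) <= 1e-12 * max(1.0, best_rss)
        if best_params is None or better or (tie and sol.x[0] < best_params[0]):
            best_params = sol.x.copy()
            best_rss = rss
            converged = bool(sol.success)
    if best_params is None:
        raise RuntimeError(
            "tube-load fit failed: no multistart converged "
            f"(n={n}, fs={fs}, bounds={bounds})"
        )
    pinned = bool(
        abs(best_params[0] - bounds.td[0]) < 1e-6
        or abs(best_params[0] - bounds.td[1]) < 1e-6
    )
    params = TubeLoadParams(td=float(best_params[0]), tau_rc=float(best_params[1]), tau_zc=float(best_params[2]))
    return params, best_rss, converged, pinned


def fit_single_tube(prox, dist, bounds=None, grid=None, seed=None) -> FitResult:
    """Per-beat single-tube fit; see :class:`cfpwv.estimators.TubeLoadPTT`."""
    from .estimators import TubeLoadPTT

    est = TubeLoadPTT(bounds=bounds, grid=grid, seed=seed).fit(prox, dist)
    return est.fit_result_


def fit_dual_tube(aortic, carotid, femoral, bounds=None, grid=None, seed=None):
    """Parallel dual-tube fit; returns ``(acPTT, afPTT, cfPTT)`` in seconds."""
    from .estimators import DualTubePTT

    est = DualTubePTT(bounds=bounds, grid=grid, seed=seed).fit(aortic, carotid, femoral)
    return est.ac_ptt_, est.af_ptt_, est.ptt_


def pwv_from_ptt(direct_distance: float, ptt: float, factor: float = 0.8) -> float:
    """Pulse wave velocity from a body-surface distance and a transit time.

    The straight-line carotid-femoral distance overestimates the effective
    aortic path, so it is corrected by ``factor`` (0.8 by convention).
    """
    if direct_distance <= 0:
        raise ValueError("distance must be > 0")
    if ptt <= 0:
        raise ValueError("ptt must be > 0")
    return factor * direct_distance / ptt
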