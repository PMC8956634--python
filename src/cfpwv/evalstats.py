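"""Agreement, repeatability and robustness statistics, plus experiment drivers.

The three assessment protocols:

* **repeatability** — ICC(1,1), the one-way random-effects single-measure
  intraclass correlation, over repeated synthetic measurement sessions;
* **accuracy** — Bland-Altman agreement (mean difference, 1.96-SD limits,
  difference-vs-mean regression for proportional bias) of estimated against
  true cfPWV;
* **robustness** — absolute cfPWV error of noisy re-measurements against the
  noiseless estimate of the same record, per SNR level, with a Friedman test
  across SNR levels per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .pipeline import estimate_ptt, preprocess_recording
from .synthgen import SyntheticTruth, degrade, generate_record

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementReport",
    "RobustnessTable",
    "icc_oneway",
    "bland_altman",
    "friedman",
    "ols_slope_test",
    "run_accuracy_experiment",
    "run_repeatability_experiment",
    "run_robustness_experiment",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS: tuple[str, ...] = ("match", "tangent", "xcorr", "tubeload")


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement summary for paired measurements ``a - b``."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope: float
    bias_intercept: float
    bias_p: float
    n: int


@dataclass
class RobustnessTable:
    """Per (method, SNR) absolute-error summary with per-method Friedman tests."""

    table: pd.DataFrame  # columns: method, snr_db, mean_abs_err, sd_abs_err, n
    friedman: dict[str, tuple[float, float]]
    errors: pd.DataFrame  # tidy: subject, rep, method, snr_db, abs_err


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def icc_oneway(x: np.ndarray) -> float:
    """One-way random-effects, single-measure ICC(1,1).

    ``x`` is an ``n_subjects x k_repeats`` matrix with no missing cells.
    ICC = (MSB - MSW) / (MSB + (k-1) MSW), where MSB/MSW are the between- and
    within-subject mean squares of the one-way ANOVA.  Values near 1 mean the
    repeats agree; > 0.75 is conventionally "good reliability".  A negative
    estimate is reported as-is with a logged note.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * float(np.sum((row_means - grand) ** 2))
    ssw = float(np.sum((x - row_means[:, None]) ** 2))
    if ssb + ssw == 0:
        raise ValueError("degenerate matrix: zero total variance")
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if icc < 0:
        logger.info("negative ICC estimate (%.3f); reported unclipped", icc)
    return float(icc)


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman agreement of ``a`` against ``b`` (differences ``a - b``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    mean = (a + b) / 2.0
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.ptp(mean) == 0 or np.ptp(diff) == 0:
        slope, intercept, p = 0.0, md, 1.0
    else:
        res = sst.linregress(mean, diff)
        slope, intercept, p = float(res.slope), float(res.intercept), float(res.pvalue)
    return AgreementReport(
        mean_diff=md,
        sd_diff=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        bias_slope=slope,
        bias_intercept=intercept,
        bias_p=p,
        n=a.size,
    )


def friedman(x: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across the columns of an ``n x k`` matrix.

    Within-row mid-ranks with the standard tie correction; the statistic is
    referred to a chi-square with ``k - 1`` degrees of freedom.  An
    all-constant matrix yields statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 matrix")
    n, k = x.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, x)
    rsum = ranks.sum(axis=0)
    s = float(np.sum((rsum - n * (k + 1) / 2.0) ** 2))
    # tie correction per row
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 1.0
    stat = 12.0 * s / (n * k * (k + 1)) / c
    p = float(sst.chi2.sf(stat, k - 1))
    return float(stat), p


def friedman_exact_p(x: np.ndarray, statistic: float | None = None) -> float:
    """Exact permutation p-value for tiny matrices (test oracle for n <= 8)."""
    from itertools import permutations, product

    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n > 8:
        raise ValueError("exact enumeration only for n <= 8")
    if statistic is None:
        statistic, _ = friedman(x)

    def stat_of(rank_rows: np.ndarray) -> float:
        rsum = rank_rows.sum(axis=0)
        s = float(np.sum((rsum - n * (k + 1) / 2.0) ** 2))
        return 12.0 * s / (n * k * (k + 1))

    perms = [np.asarray(p, dtype=float) for p in permutations(range(1, k + 1))]
    count = 0
    total = 0
    for combo in product(range(len(perms)), repeat=n):
        rows = np.vstack([perms[i] for i in combo])
        if stat_of(rows) >= statistic - 1e-12:
            count += 1
        total += 1
    return count / total


def ols_slope_test(x, y) -> tuple[float, float, float]:
    """Ordinary least squares with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = sst.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _estimate_pwv(
    truth: SyntheticTruth,
    methods,
    seed: int,
    mode: str = "sequential",
    snr_db: float = np.inf,
    drift_amp: float = 0.0,
    drift_hz: float = 0.2,
    decimate: bool = False,
    noise_seed: int | None = None,
    records=None,
) -> dict[str, float]:
    """Generate, degrade, preprocess and estimate one subject's cfPWV.

    ``records`` may carry a pre-generated ``(aortic, carotid, femoral)``
    triple to avoid regenerating the same clean session.
    """
    if records is None:
        aortic, carotid, femoral, _ = generate_record(truth.spec, seed, mode=mode)
    else:
        aortic, carotid, femoral = records
    if decimate or drift_amp or not np.isinf(snr_db):
        fs_out = truth.spec.fs_record if decimate else None
        ns = noise_seed if noise_seed is not None else seed
        carotid = degrade(
            carotid, snr_db=snr_db, drift_amp=drift_amp, drift_hz=drift_hz,
            seed=ns, fs_out=fs_out,
        )
        femoral = degrade(
            femoral, snr_db=snr_db, drift_amp=drift_amp, drift_hz=drift_hz,
            seed=ns + 1, fs_out=fs_out,
        )
        carotid = preprocess_recording(carotid)
        femoral = preprocess_recording(femoral)
        if "dualtube" in methods:
            aortic = preprocess_recording(aortic)
    out: dict[str, float] = {}
    for m in methods:
        try:
            est = estimate_ptt(carotid, femoral, method=m, aortic=aortic)
            out[m] = est.pwv(truth.spec.distance_cf, factor=truth.distance_factor)
        except Exception as exc:
            logger.warning("estimator %s failed on subject seed %d: %s", m, truth.seed, exc)
            out[m] = np.nan
    return out


def run_accuracy_experiment(
    cohort: list[SyntheticTruth],
    methods=DEFAULT_METHODS,
    seed: int = 0,
    mode: str = "simultaneous",
) -> tuple[dict[str, AgreementReport], pd.DataFrame]:
    """Estimated-vs-true cfPWV agreement per method over a clean cohort.

    Records are generated without measurement degradation (the analogue of
    evaluating against simulated numerical data with known truth).  Subjects
    on which an estimator fails are excluded from that estimator's report,
    with the count logged.
    """
    rows = []
    for i, truth in enumerate(cohort):
        est = _estimate_pwv(truth, methods, seed=truth.seed, mode=mode)
        for m, v in est.items():
            rows.append(
                {"subject": i, "method": m, "pwv_est": v, "pwv_true": truth.cf_pwv_true}
            )
    table = pd.DataFrame(rows)
    reports: dict[str, AgreementReport] = {}
    for m in methods:
        sub = table[table.method == m].dropna(subset=["pwv_est"])
        dropped = (table.method == m).sum() - len(sub)
        if dropped:
            logger.warning("accuracy: %d subjects excluded for method %s", dropped, m)
        reports[m] = bland_altman(sub.pwv_est.to_numpy(), sub.pwv_true.to_numpy())
    return reports, table


def run_repeatability_experiment(
    cohort: list[SyntheticTruth],
    repeats: int = 3,
    methods=DEFAULT_METHODS,
    seed: int = 0,
    snr_db: float = np.inf,
    drift_amp: float = 2.0,
    decimate: bool = True,
) -> tuple[dict[str, float], pd.DataFrame]:
    """ICC(1,1) of repeated synthetic measurements per method.

    Each repeat is a re-measurement of the same subject's session with an
    independent degradation-noise seed at ``snr_db`` (truth and session held
    fixed); the ICC is computed over the ``n_subjects x repeats`` cfPWV
    matrix for each method.  With no noise the repeats are identical and the
    ICC is exactly 1.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    rows = []
    for i, truth in enumerate(cohort):
        recs = generate_record(truth.spec, truth.seed, mode="sequential")[:3]
        ss = np.random.SeedSequence([seed, truth.seed])
        rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(repeats)]
        for j, rs in enumerate(rep_seeds):
            est = _estimate_pwv(
                truth, methods, seed=truth.seed, mode="sequential",
                snr_db=snr_db, decimate=decimate, drift_amp=drift_amp, noise_seed=rs,
                records=recs,
            )
            for m, v in est.items():
                rows.append({"subject": i, "repeat": j, "method": m, "pwv": v})
    table = pd.DataFrame(rows)
    iccs: dict[str, float] = {}
    for m in methods:
        mat = (
            table[table.method == m]
            .pivot(index="subject", columns="repeat", values="pwv")
            .dropna()
            .to_numpy()
        )
        iccs[m] = icc_oneway(mat)
    return iccs, table


def run_robustness_experiment(
    cohort: list[SyntheticTruth],
    methods=DEFAULT_METHODS,
    snr_list=(20.0, 15.0, 10.0, 5.0),
    reps: int = 20,
    seed: int = 0,
    drift_amp: float = 2.0,
) -> RobustnessTable:
    """Noise tolerance: |cfPWV(noisy) - cfPWV(noiseless)| per method and SNR.

    The error baseline is the estimate from the same degraded record without
    added noise (the "effectively noiseless" signal), so an ``snr = inf``
    condition gives an exactly zero error row.  A Friedman test across SNR
    levels (rows = subject x rep) is run per method.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    err_rows = []
    for i, truth in enumerate(cohort):
        recs = generate_record(truth.spec, truth.seed, mode="sequential")[:3]
        base = _estimate_pwv(
            truth, methods, seed=truth.seed, mode="sequential",
            snr_db=np.inf, decimate=True, drift_amp=drift_amp, records=recs,
        )
        ss = np.random.SeedSequence([seed, truth.seed, 1])
        noise_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(reps * len(snr_list))]
        for r in range(reps):
            for j, snr in enumerate(snr_list):
                ns = noise_seeds[r * len(snr_list) + j]
                est = _estimate_pwv(
                    truth, methods, seed=truth.seed, mode="sequential",
                    snr_db=snr, decimate=True, drift_amp=drift_amp, noise_seed=ns,
                    records=recs,
                )
                for m in methods:
                    err_rows.append(
                        {
                            "subject": i,
                            "rep": r,
                            "method": m,
                            "snr_db": snr,
                            "abs_err": abs(est[m] - base[m]),
                        }
                    )
    errors = pd.DataFrame(err_rows)
    summary = (
        errors.groupby(["method", "snr_db"], as_index=False)
        .agg(mean_abs_err=("abs_err", "mean"), sd_abs_err=("abs_err", "std"), n=("abs_err", "size"))
    )
    fr: dict[str, tuple[float, float]] = {}
    if len(snr_list) >= 2:
        for m in methods:
            mat = (
                errors[errors.method == m]
                .pivot(index=["subject", "rep"], columns="snr_db", values="abs_err")
                .dropna()
                .to_numpy()
            )
            if mat.shape[0] >= 2:
                fr[m] = friedman(mat)
    return RobustnessTable(table=summary, friedman=fr, errors=errors)
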