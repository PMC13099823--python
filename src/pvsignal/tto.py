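"""Time-to-onset (TTO) analysis with a Weibull failure-type test.

TTO is the interval in days from therapy initiation to adverse-event onset.
Reports with incomplete date information or with events recorded before
therapy started are excluded (and tallied by reason).  The retained onset
times are summarized (median, IQR, occurrence-time histogram) and fitted by
maximum likelihood to a two-parameter Weibull density

    f(t) = (beta/alpha) (t/alpha)^(beta-1) exp(-(t/alpha)^beta),

whose shape parameter classifies the hazard: a 95% CI for beta entirely
below 1 indicates an early-failure pattern (risk decreasing with time on
therapy), entirely above 1 a wear-out pattern, and a CI containing 1 a
random (constant-hazard) pattern.

The MLE uses the profile likelihood: for fixed beta the scale has the
closed form alpha = (mean t^beta)^(1/beta), leaving a one-dimensional
monotone score equation for beta that is solved by bracketing.  This makes
the fit exactly scale-equivariant.  Wald CIs are computed on log(alpha),
log(beta) from the observed information and back-transformed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .ingest import Report

Z975 = 1.959963984540054

#: Occurrence-time histogram buckets (days); upper bound inclusive.
BUCKETS = ("0-30", "31-60", "61-90", "91-120", "121-150", "151-180", "181-360", ">360")
_BUCKET_EDGES = (30, 60, 90, 120, 150, 180, 360)

#: Day-0 onsets enter the likelihood as half a day (log(0) guard); the
#: empirical median/IQR always use the raw values.
ZERO_SHIFT = 0.5


class FitError(RuntimeError):
    """Degenerate likelihood (e.g. all onset times identical)."""


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    tto_days: int
    bucket: str


@dataclass
class WeibullFit:
    n: int
    alpha: float
    alpha_ci: tuple[float, float]
    beta: float
    beta_ci: tuple[float, float]
    tto_median: float
    tto_iqr: tuple[float, float]
    failure_type: str  # "early" / "random" / "wear-out"


def bucket_for(tto_days: int) -> str:
    for label, edge in zip(BUCKETS, _BUCKET_EDGES):
        if tto_days <= edge:
            return label
    return ">360"


def compute_tto(reports: Sequence[Report]) -> tuple[list[TTORecord], Counter]:
    """Onset intervals per report, with exclusions tallied by reason.

    Exclusion reasons: missing_event_date, missing_start_date,
    incomplete_date (either date partial), negative (event precedes
    therapy start).  excluded + included = input count.
    """
    records: list[TTORecord] = []
    excluded: Counter = Counter()
    for r in reports:
        if r.event_date is None:
            excluded["missing_event_date"] += 1
            continue
        if r.therapy_start is None:
            excluded["missing_start_date"] += 1
            continue
        if not (r.event_date.complete and r.therapy_start.complete):
            excluded["incomplete_date"] += 1
            continue
        tto = (r.event_date.to_date() - r.therapy_start.to_date()).days
        if tto < 0:
            excluded["negative"] += 1
            continue
        records.append(TTORecord(r.primaryid, tto, bucket_for(tto)))
    return records, excluded


def bucket_distribution(records: Sequence[TTORecord]) -> dict[str, int]:
    """Counts over the eight occurrence-time buckets; values sum to n."""
    counts = dict.fromkeys(BUCKETS, 0)
    for rec in records:
        counts[rec.bucket] += 1
    return counts


# ---------------------------------------------------------------------------
# Weibull MLE


def _shape_score(beta: float, t: np.ndarray, log_t: np.ndarray) -> float:
    """d(profile log-likelihood)/d(beta) up to a positive factor n/beta ...

    With alpha profiled out, the stationarity condition for beta is
    sum(t^b log t)/sum(t^b) - 1/b - mean(log t) = 0, increasing in b.
    """
    tb = np.power(t, beta)
    return float(np.dot(tb, log_t) / np.sum(tb) - 1.0 / beta - np.mean(log_t))


def weibull_mle(times: Sequence[float]) -> tuple[float, float]:
    """Profile-likelihood MLE of (scale alpha, shape beta); times > 0."""
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("weibull_mle requires strictly positive times")
    if t.size < 2 or np.ptp(t) == 0:
        raise FitError("degenerate sample: all onset times identical")
    log_t = np.log(t)
    lo, hi = 1e-3, 1.0
    while _shape_score(hi, t, log_t) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise FitError("shape score has no root in (0, 1e4]")
    while _shape_score(lo, t, log_t) > 0:
        lo /= 2.0
        if lo < 1e-8:
            raise FitError("shape score has no root in [1e-8, ...)")
    beta = optimize.brentq(_shape_score, lo, hi, args=(t, log_t), xtol=1e-12, rtol=1e-14)
    alpha = float(np.mean(np.power(t, beta)) ** (1.0 / beta))
    return alpha, float(beta)


def weibull_loglik(times: Sequence[float], alpha: float, beta: float) -> float:
    t = np.asarray(times, dtype=float)
    z = t / alpha
    return float(
        t.size * (math.log(beta) - math.log(alpha))
        + (beta - 1.0) * np.sum(np.log(z))
        - np.sum(np.power(z, beta))
    )


def _log_param_hessian(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Observed information of -loglik in (log alpha, log beta), by central
    finite differences (invariant under rescaling of t)."""
    la, lb = math.log(alpha), math.log(beta)
    h = 1e-4

    def nll(p):
        return -weibull_loglik(t, math.exp(p[0]), math.exp(p[1]))

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            p = np.array([la, lb])
            pp, pm, mp, mm = (p.copy() for _ in range(4))
            pp[i] += h; pp[j] += h
            pm[i] += h; pm[j] -= h
            mp[i] -= h; mp[j] += h
            mm[i] -= h; mm[j] -= h
            hess[i, j] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h * h)
    return hess


def fit_weibull(records: Sequence[TTORecord] | Sequence[int]) -> WeibullFit:
    """Fit the onset-time distribution and classify the failure type.

    Accepts TTORecords or raw day counts.  Requires n >= 10.  Zero-day
    onsets are shifted by ``ZERO_SHIFT`` for the likelihood only.
    """
    raw = np.array(
        [r.tto_days if isinstance(r, TTORecord) else r for r in records], dtype=float
    )
    if raw.size < 10:
        raise FitError(f"need at least 10 onset times, got {raw.size}")
    t = np.where(raw == 0, ZERO_SHIFT, raw)
    alpha, beta = weibull_mle(t)

    info = _log_param_hessian(t, alpha, beta)
    cov = np.linalg.inv(info)
    se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    alpha_ci = (alpha * math.exp(-Z975 * se_la), alpha * math.exp(Z975 * se_la))
    beta_ci = (beta * math.exp(-Z975 * se_lb), beta * math.exp(Z975 * se_lb))

    if beta_ci[1] < 1.0:
        failure = "early"
    elif beta_ci[0] > 1.0:
        failure = "wear-out"
    else:
        failure = "random"

    q1, med, q3 = np.percentile(raw, [25, 50, 75])
    return WeibullFit(
        n=int(raw.size),
        alpha=alpha,
        alpha_ci=alpha_ci,
        beta=beta,
        beta_ci=beta_ci,
        tto_median=float(med),
        tto_iqr=(float(q1), float(q3)),
        failure_type=failure,
    )


def fit_to_row(fit: WeibullFit) -> dict:
    """Summary-row export: n, median (IQR), scale and shape with CIs,
    failure type."""
    return {
        "n": fit.n,
        "tto_median": fit.tto_median,
        "tto_q1": fit.tto_iqr[0],
        "tto_q3": fit.tto_iqr[1],
        "alpha": fit.alpha,
        "alpha_lo": fit.alpha_ci[0],
        "alpha_hi": fit.alpha_ci[1],
        "beta": fit.beta,
        "beta_lo": fit.beta_ci[0],
        "beta_hi": fit.beta_ci[1],
        "failure_type": fit.failure_type,
    }
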