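"""Disproportionality analysis of drug-event pairs in spontaneous reports.

For each MedDRA preferred term (PT) a 2x2 report-level contingency table is
built against the rest of the database:

    ==============  ==========  ===========
                    PT present  other PTs
    target drug       a            b
    other drugs       c            d
    ==============  ==========  ===========

Four statistics are computed per table, each with the screening threshold
conventionally used in FAERS signal-detection studies:

* reporting odds ratio (ROR) with a 95% Wald CI on the log scale
  (signal: a >= 3 and CI lower bound > 1);
* proportional reporting ratio (PRR) with a Yates-corrected chi-square
  (signal: a >= 3, PRR >= 2, chi2 >= 4 — the MHRA composite criterion);
* Bayesian confidence propagation neural network information component
  (IC), computed by Monte Carlo under the standard unit-expectation beta
  priors (signal: IC025 > 0);
* multi-item gamma Poisson shrinker EBGM under the two-component gamma
  mixture prior (signal: EB05 > 2).

A PT is a consensus signal only when all four flags are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .ingest import Report

Z975 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one (drug, event) pair."""

    a: int  # target drug, PT
    b: int  # target drug, other PTs
    c: int  # other drugs, PT
    d: int  # other drugs, other PTs

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe continuity correction: +0.5 everywhere, applied
        only when some cell is zero."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


@dataclass(frozen=True)
class PriorParams:
    """MGPS two-gamma mixture prior (shape/rate pairs and mixing weight).

    Defaults are the published fit to FDA data that FAERS disproportionality
    studies conventionally reuse.
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    w: float = 1.0 / 3.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("MGPS prior parameters must be positive")
        if not 0 < self.w < 1:
            raise ValueError("MGPS mixture weight must be in (0, 1)")


@dataclass
class SignalConfig:
    """Thresholds, priors and seeds for the four-algorithm screen."""

    min_count: int = 3
    ror_ci_lower: float = 1.0
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    ic025_threshold: float = 0.0
    eb05_threshold: float = 2.0
    yates: bool = True
    bcpnn_draws: int = 100_000
    bcpnn_stat: str = "expectation"  # or "median"
    seed: int = 20090924
    mgps_prior: PriorParams = field(default_factory=PriorParams)


@dataclass
class SignalResult:
    pt: str
    soc: Optional[str]
    table: ContingencyTable
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float
    ror_flag: bool
    prr_flag: bool
    bcpnn_flag: bool
    mgps_flag: bool

    @property
    def consensus(self) -> bool:
        return self.ror_flag and self.prr_flag and self.bcpnn_flag and self.mgps_flag


# ---------------------------------------------------------------------------
# table construction


def build_tables(
    target: Sequence[Report], background: Sequence[Report]
) -> dict[str, ContingencyTable]:
    """One 2x2 table per PT occurring anywhere in the database.

    Counting is report-level: a report contributes at most one count to a
    given cell for a given PT, however many times it lists the term.
    """
    if not target:
        raise ValueError("no target reports")
    if not background:
        raise ValueError("no background reports")
    n_t = len(target)
    n_b = len(background)
    a_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    for r in target:
        for pt in set(r.events):
            a_counts[pt] = a_counts.get(pt, 0) + 1
    for r in background:
        for pt in set(r.events):
            c_counts[pt] = c_counts.get(pt, 0) + 1
    tables = {}
    for pt in sorted(set(a_counts) | set(c_counts)):
        a = a_counts.get(pt, 0)
        c = c_counts.get(pt, 0)
        tables[pt] = ContingencyTable(a=a, b=n_t - a, c=c, d=n_b - c)
    return tables


# ---------------------------------------------------------------------------
# frequentist statistics


def ror_stats(
    t: ContingencyTable, ci_lower_threshold: float = 1.0, min_count: int = 3
) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with 95% Wald CI; flag = (a>=3 and CI_lo > 1)."""
    a, b, c, d = t.corrected()
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z975 * se)
    hi = math.exp(math.log(ror) + Z975 * se)
    flag = t.a >= min_count and lo > ci_lower_threshold
    return ror, lo, hi, flag


def prr_stats(
    t: ContingencyTable,
    prr_threshold: float = 2.0,
    chi2_threshold: float = 4.0,
    min_count: int = 3,
    yates: bool = True,
) -> tuple[float, float, bool]:
    """Proportional reporting ratio and the 2x2 chi-square (MHRA criterion)."""
    a, b, c, d = t.corrected()
    prr = (a / (a + b)) / (c / (c + d))
    chi2, _, _, _ = stats.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=yates
    )
    flag = t.a >= min_count and prr >= prr_threshold and chi2 >= chi2_threshold
    return prr, float(chi2), flag


# ---------------------------------------------------------------------------
# BCPNN information component

def _bcpnn_posteriors(t: ContingencyTable):
    """Posterior beta laws for p_xy, p_x, p_y under the standard BCPNN priors.

    Margins get Beta(1, 1) priors; the joint cell gets Beta(g1, g - g1) with
    g1 = 1 and g chosen so the prior expectation of the IC is zero:
    E[p_xy] = E[p_x] E[p_y].
    """
    n = t.n
    nx = t.a + t.b
    ny = t.a + t.c
    g1 = 1.0
    g = g1 * (n + 2) ** 2 / ((nx + 1) * (ny + 1))
    joint = (g1 + t.a, g - g1 + n - t.a)
    margin_x = (1.0 + nx, 1.0 + n - nx)
    margin_y = (1.0 + ny, 1.0 + n - ny)
    return joint, margin_x, margin_y


def bcpnn_ic(
    t: ContingencyTable,
    n_draws: int = 100_000,
    seed: int = 0,
    stat: str = "expectation",
    ic025_threshold: float = 0.0,
) -> tuple[float, float, bool]:
    """Monte-Carlo IC and its 2.5th-percentile credible bound.

    Draws the joint and the two marginal reporting probabilities from their
    independent beta posteriors and forms IC = log2(p_xy / (p_x p_y)).
    ``stat`` selects the posterior expectation (default) or median as the
    point estimate; the flag is IC025 > 0.
    """
    if n_draws < 10_000:
        raise ValueError("bcpnn_ic requires n_draws >= 10000")
    joint, mx, my = _bcpnn_posteriors(t)
    rng = np.random.default_rng(seed)
    p_xy = rng.beta(*joint, size=n_draws)
    p_x = rng.beta(*mx, size=n_draws)
    p_y = rng.beta(*my, size=n_draws)
    ic_draws = np.log2(p_xy) - np.log2(p_x) - np.log2(p_y)
    if stat == "expectation":
        ic = float(np.mean(ic_draws))
    elif stat == "median":
        ic = float(np.median(ic_draws))
    else:
        raise ValueError(f"unknown BCPNN point statistic {stat!r}")
    ic025 = float(np.quantile(ic_draws, 0.025))
    return ic, ic025, ic025 > ic025_threshold


def bcpnn_ic_approx(t: ContingencyTable, n_quad: int = 41) -> tuple[float, float]:
    """Deterministic approximation to the Monte-Carlo IC (no sampling).

    The posterior expectation of log2 of a Beta(A, B) variable is
    (psi(A) - psi(A+B)) / ln 2, so the IC expectation is exact.  For IC025
    the joint-cell term — which is strongly skewed when ``a`` is small — is
    kept exact through the regularized incomplete beta CDF, while the two
    marginal terms (whose shape counts are large in practice) are treated
    as a normal via digamma/trigamma moments and integrated out by
    Gauss-Hermite quadrature; the quantile is then root-found on the
    resulting mixture CDF.
    """
    ln2 = math.log(2.0)
    (aj, bj), mx, my = _bcpnn_posteriors(t)
    mu_w = 0.0
    var_w = 0.0
    for al, be in (mx, my):
        mu_w -= (special.digamma(al) - special.digamma(al + be)) / ln2
        var_w += (special.polygamma(1, al) - special.polygamma(1, al + be)) / ln2**2
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    w = mu_w + math.sqrt(var_w) * nodes
    wt = weights / weights.sum()

    def cdf(q: float) -> float:
        x = np.minimum(np.exp2(q - w), 1.0)
        return float(np.dot(wt, special.betainc(aj, bj, x)))

    mean_l1 = (special.digamma(aj) - special.digamma(aj + bj)) / ln2
    var_l1 = (special.polygamma(1, aj) - special.polygamma(1, aj + bj)) / ln2**2
    mean = mean_l1 + mu_w
    spread = 12.0 * math.sqrt(var_l1 + var_w) + 1.0
    ic025 = optimize.brentq(
        lambda q: cdf(q) - 0.025, mean - spread, mean + spread, xtol=1e-10
    )
    return mean, float(ic025)


# ---------------------------------------------------------------------------
# MGPS / EBGM


def _mgps_posterior(t: ContingencyTable, prior: PriorParams):
    """Posterior over the relative reporting rate lambda given a ~ Poisson(lambda E).

    Conjugacy gives a two-component gamma mixture with component weights
    updated through the negative-binomial marginal likelihoods.
    """
    e = t.expected
    if e <= 0:
        raise ValueError("expected count must be positive for MGPS")
    a = t.a
    # marginal (prior-predictive) log-likelihood of each component
    log_m1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    log_m2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    log_w1 = math.log(prior.w) + log_m1
    log_w2 = math.log(1 - prior.w) + log_m2
    norm = np.logaddexp(log_w1, log_w2)
    q1 = math.exp(log_w1 - norm)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + e, prior.beta2 + e)
    return q1, shapes, rates


def mgps_ebgm(
    t: ContingencyTable,
    prior: PriorParams | None = None,
    eb05_threshold: float = 2.0,
) -> tuple[float, float, bool]:
    """Empirical-Bayes geometric mean and its 5th-percentile bound.

    EBGM = 2^{E[log2 lambda | a]} via the digamma identity for gamma
    expectations; EB05 solves the posterior mixture CDF = 0.05 by monotone
    root-finding.  Flag: EB05 > 2.
    """
    prior = prior or PriorParams()
    q1, (s1, s2), (r1, r2) = _mgps_posterior(t, prior)
    e_log = q1 * (special.digamma(s1) - math.log(r1)) + (1 - q1) * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(e_log)

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    lo = min(stats.gamma.ppf(0.01, s1, scale=1 / r1), stats.gamma.ppf(0.01, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(0.2, s1, scale=1 / r1), stats.gamma.ppf(0.2, s2, scale=1 / r2))
    lo = max(lo, 1e-300)
    while cdf(hi) < 0.05:
        hi *= 2
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return ebgm, eb05, eb05 > eb05_threshold


def fit_mgps_prior(
    tables: Mapping[str, ContingencyTable], init: PriorParams | None = None
) -> PriorParams:
    """Re-estimate the five MGPS hyperparameters by maximizing the marginal
    negative-binomial likelihood over all PT tables (optional; off by default)."""
    init = init or PriorParams()
    counts = np.array([t.a for t in tables.values()], dtype=float)
    expected = np.array([t.expected for t in tables.values()], dtype=float)

    def nll(theta):
        a1, b1, a2, b2 = np.exp(theta[:4])
        w = 1 / (1 + np.exp(-theta[4]))
        l1 = stats.nbinom.logpmf(counts, a1, b1 / (b1 + expected))
        l2 = stats.nbinom.logpmf(counts, a2, b2 / (b2 + expected))
        return -np.sum(np.logaddexp(np.log(w) + l1, np.log1p(-w) + l2))

    x0 = np.array([
        math.log(init.alpha1), math.log(init.beta1),
        math.log(init.alpha2), math.log(init.beta2),
        math.log(init.w / (1 - init.w)),
    ])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-6, "fatol": 1e-8})
    a1, b1, a2, b2 = np.exp(res.x[:4])
    w = float(1 / (1 + np.exp(-res.x[4])))
    return PriorParams(float(a1), float(b1), float(a2), float(b2), w)


# ---------------------------------------------------------------------------
# the consensus screen


def _pt_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))


def detect_signals(
    tables: Mapping[str, ContingencyTable],
    config: SignalConfig | None = None,
    pt_to_soc: Mapping[str, str] | None = None,
) -> list[SignalResult]:
    """Run all four algorithms on every PT with at least ``min_count`` target
    reports; a consensus signal requires all four flags.

    Results are sorted by descending ROR, ties broken by larger ``a`` then PT
    lexicographically, so reports are deterministic.
    """
    config = config or SignalConfig()
    results: list[SignalResult] = []
    for index, pt in enumerate(sorted(tables)):
        t = tables[pt]
        if t.a < config.min_count:
            continue
        ror, lo, hi, ror_flag = ror_stats(t, config.ror_ci_lower, config.min_count)
        prr, chi2, prr_flag = prr_stats(
            t, config.prr_threshold, config.chi2_threshold, config.min_count, config.yates
        )
        ic, ic025, bcpnn_flag = bcpnn_ic(
            t,
            n_draws=config.bcpnn_draws,
            seed=_pt_seed(config.seed, index),
            stat=config.bcpnn_stat,
            ic025_threshold=config.ic025_threshold,
        )
        ebgm, eb05, mgps_flag = mgps_ebgm(t, config.mgps_prior, config.eb05_threshold)
        results.append(
            SignalResult(
                pt=pt,
                soc=pt_to_soc.get(pt) if pt_to_soc else None,
                table=t,
                ror=ror, ror_lo=lo, ror_hi=hi,
                prr=prr, chi2=chi2,
                ic=ic, ic025=ic025,
                ebgm=ebgm, eb05=eb05,
                ror_flag=ror_flag, prr_flag=prr_flag,
                bcpnn_flag=bcpnn_flag, mgps_flag=mgps_flag,
            )
        )
    results.sort(key=lambda r: (-r.ror, -r.table.a, r.pt))
    return results


def signals_to_frame(results: Sequence[SignalResult]):
    """Tabular export: one row per PT with all statistics and flags."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pt": [r.pt for r in results],
            "soc": [r.soc for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "ror": [r.ror for r in results],
            "ror_lo": [r.ror_lo for r in results],
            "ror_hi": [r.ror_hi for r in results],
            "prr": [r.prr for r in results],
            "chi2": [r.chi2 for r in results],
            "ic": [r.ic for r in results],
            "ic025": [r.ic025 for r in results],
            "ebgm": [r.ebgm for r in results],
            "eb05": [r.eb05 for r in results],
            "ror_flag": [r.ror_flag for r in results],
            "prr_flag": [r.prr_flag for r in results],
            "bcpnn_flag": [r.bcpnn_flag for r in results],
            "mgps_flag": [r.mgps_flag for r in results],
            "consensus": [r.consensus for r in results],
        }
    )
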