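"""Stratified signal screening and sex-difference testing.

Subgroup screens restrict both the target and the background population to
one stratum (sex, age group, or report seriousness) before building the
2x2 tables; the reporting-odds-ratio criterion (a >= 3 and 95% CI lower
bound > 1) is the screening rule, and top-k listings are ranked by report
frequency.

The sex-difference test compares, within target-drug reports only, female
versus male reporting of each PT: an ROR > 1 with CI lower bound > 1 marks
a female-biased term, ROR < 1 with CI upper bound < 1 a male-biased one.
P-values come from the chi-square test (Fisher's exact when any expected
cell is below 5) and are adjusted across PTs by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import Report
from .signals import (
    ContingencyTable,
    SignalConfig,
    SignalResult,
    build_tables,
    detect_signals,
    ror_stats,
)

logger = logging.getLogger(__name__)

AXES = {
    "sex": ("F", "M"),
    "age_group": ("<18", "18-44", "45-64", ">=65"),
    "age_binary": ("<65", ">=65"),
    "report_type": ("serious", "non-serious"),
}


@dataclass(frozen=True)
class SubgroupSpec:
    axis: str
    level: str

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"unknown subgroup axis {self.axis!r}")
        if self.level not in AXES[self.axis]:
            raise ValueError(
                f"level {self.level!r} invalid for axis {self.axis!r}; "
                f"expected one of {AXES[self.axis]}"
            )


@dataclass
class SexDifferenceResult:
    pt: str
    table: ContingencyTable  # (female vs male) x (PT vs other PTs), target drug only
    ror: float
    ror_lo: float
    ror_hi: float
    direction: str  # "female-biased" / "male-biased" / "none"
    p_value: float
    fdr_q: float


def in_stratum(report: Report, spec: SubgroupSpec) -> bool:
    """Stratum membership; reports with the attribute unknown never match."""
    if spec.axis == "sex":
        return report.sex == spec.level
    if spec.axis == "age_group":
        return report.age_group == spec.level
    if spec.axis == "age_binary":
        if report.age_years is None:
            return False
        return (report.age_years >= 65) == (spec.level == ">=65")
    if spec.axis == "report_type":
        return report.serious == (spec.level == "serious")
    raise AssertionError(spec.axis)


def stratified_signals(
    target: Sequence[Report],
    background: Sequence[Report],
    spec: SubgroupSpec,
    config: SignalConfig | None = None,
    pt_to_soc=None,
) -> list[SignalResult]:
    """Four-algorithm screen within one stratum, ranked by frequency.

    Both populations are restricted to the stratum before table building.
    The subgroup screening rule is the ROR flag; the full statistics are
    still computed so the output carries everything.  Results are sorted by
    descending target count ``a`` (then PT) for top-k frequency listings.
    """
    t_sub = [r for r in target if in_stratum(r, spec)]
    b_sub = [r for r in background if in_stratum(r, spec)]
    if not t_sub or not b_sub:
        logger.warning(
            "stratified_signals: empty stratum %s=%s (target %d, background %d)",
            spec.axis, spec.level, len(t_sub), len(b_sub),
        )
        return []
    tables = build_tables(t_sub, b_sub)
    results = detect_signals(tables, config, pt_to_soc)
    results.sort(key=lambda r: (-r.table.a, r.pt))
    return results


def sex_difference(
    target_reports: Sequence[Report],
    pts: Optional[Sequence[str]] = None,
    min_count: int = 1,
) -> list[SexDifferenceResult]:
    """Female-vs-male disproportionality per PT among target-drug reports.

    ``pts`` restricts the test set (e.g. the consensus signal list); by
    default every PT reported for the target drug in either sex is tested.
    PTs absent in both sexes are skipped and logged.
    """
    females = [r for r in target_reports if r.sex == "F"]
    males = [r for r in target_reports if r.sex == "M"]
    if not females or not males:
        raise ValueError("sex_difference requires reports from both sexes")

    def count(pop, pt):
        return sum(1 for r in pop if pt in r.events)

    if pts is None:
        pts = sorted({pt for r in females + males for pt in r.events})

    rows = []
    for pt in pts:
        a = count(females, pt)
        c = count(males, pt)
        if a + c < min_count or (a == 0 and c == 0):
            logger.info("sex_difference: skipping %r (absent in both sexes)", pt)
            continue
        t = ContingencyTable(a=a, b=len(females) - a, c=c, d=len(males) - c)
        ror, lo, hi, _ = ror_stats(t, min_count=0)
        if ror > 1 and lo > 1:
            direction = "female-biased"
        elif ror < 1 and hi < 1:
            direction = "male-biased"
        else:
            direction = "none"
        obs = np.array([[t.a, t.b], [t.c, t.d]])
        expected = stats.contingency.expected_freq(obs)
        if expected.min() < 5:
            _, p = stats.fisher_exact(obs)
        else:
            chi2, p, _, _ = stats.chi2_contingency(obs, correction=True)
        rows.append((pt, t, ror, lo, hi, direction, float(p)))

    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[6] for r in rows], method="fdr_bh")
    return [
        SexDifferenceResult(pt, t, ror, lo, hi, direction, p, float(q))
        for (pt, t, ror, lo, hi, direction, p), q in zip(rows, qvals)
    ]


def volcano_frame(results: Sequence[SexDifferenceResult]):
    """Volcano-ready export: log2 ROR, -log10 p, FDR q per PT."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pt": [r.pt for r in results],
            "log2_ror": [math.log2(r.ror) for r in results],
            "neg_log10_p": [-math.log10(max(r.p_value, 1e-300)) for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "direction": [r.direction for r in results],
        }
    )
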