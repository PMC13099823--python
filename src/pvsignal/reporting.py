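"""Descriptive outputs: characteristics table, SOC distribution, outcome-by-PT.

Percentages are computed as 100 * count / denominator and rounded half-up
to two decimals, which reproduces printed case-proportion tables exactly
from their integer counts.  Single-valued sections sum to 100% up to
rounding; the outcome section is patient-level and multi-valued, so its
percentages may exceed 100%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .ingest import DictionaryTables, Report, OUTCOME_CODES
from .tto import BUCKETS, bucket_distribution, compute_tto

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention to prevent permanent impairment/damage",
    "OT": "Other",
}


@dataclass(frozen=True)
class FrequencyRow:
    label: str
    count: int
    pct: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def pct_of(count: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator)


def _freq_rows(counter: Mapping[str, int], denominator: int, order=None) -> list[FrequencyRow]:
    labels = order if order is not None else sorted(counter)
    return [FrequencyRow(lab, counter.get(lab, 0), pct_of(counter.get(lab, 0), denominator))
            for lab in labels]


def characteristics_table(reports: Sequence[Report], top_countries: int = 5) -> dict[str, list[FrequencyRow]]:
    """Sectioned report-characteristics table (denominator = report count).

    Sections: sex, age group, report year, reporter, top countries,
    outcomes (patient-level, multi-valued), adverse-event occurrence time.
    """
    n = len(reports)
    sections: dict[str, list[FrequencyRow]] = {}

    sex_counts = Counter(
        {"Female": 0, "Male": 0, "Not specified": 0}
    )
    for r in reports:
        sex_counts[{"F": "Female", "M": "Male"}.get(r.sex, "Not specified")] += 1
    sections["sex"] = _freq_rows(sex_counts, n, ["Female", "Male", "Not specified"])

    age_counts = Counter()
    for r in reports:
        age_counts[{"unknown": "Not specified"}.get(r.age_group, r.age_group)] += 1
    sections["age_group"] = _freq_rows(
        age_counts, n, ["<18", "18-44", "45-64", ">=65", "Not specified"]
    )

    year_counts = Counter(str(r.report_year) for r in reports if r.report_year)
    n_missing_year = sum(1 for r in reports if not r.report_year)
    order = sorted(year_counts)
    if n_missing_year:
        year_counts["Not specified"] = n_missing_year
        order.append("Not specified")
    sections["report_year"] = _freq_rows(year_counts, n, order)

    rep_counts = Counter()
    for r in reports:
        rep_counts[{"unknown": "Not specified"}.get(r.reporter, r.reporter.capitalize())] += 1
    sections["reporter"] = _freq_rows(rep_counts, n, sorted(rep_counts))

    country_counts = Counter(r.country for r in reports if r.country)
    top = [c for c, _ in sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]]
    sections["countries"] = _freq_rows(country_counts, n, top)

    outcome_counts = Counter()
    for r in reports:
        for code in r.outcomes:
            outcome_counts[code] += 1
    sections["outcomes"] = [
        FrequencyRow(OUTCOME_LABELS[code], outcome_counts.get(code, 0),
                     pct_of(outcome_counts.get(code, 0), n))
        for code in ("LT", "HO", "DS", "DE", "CA", "RI", "OT")
    ]

    records, excluded = compute_tto(reports)
    buckets = bucket_distribution(records)
    rows = [FrequencyRow(f"{lab} d", buckets[lab], pct_of(buckets[lab], n)) for lab in BUCKETS]
    n_excluded = sum(excluded.values())
    rows.append(FrequencyRow("Missing or outlier (<0)", n_excluded, pct_of(n_excluded, n)))
    sections["tto_bucket"] = rows
    return sections


def tier_for(pct: float) -> str:
    """SOC frequency tier: primary > 5%, secondary 1-5% (inclusive), rare < 1%."""
    if pct > 5.0:
        return "primary"
    if pct >= 1.0:
        return "secondary"
    return "rare"


def soc_distribution(
    reports: Sequence[Report], dictionaries: DictionaryTables
) -> pd.DataFrame:
    """AE counts per system organ class with frequency tiers.

    The denominator is the total number of AE instances (report-PT pairs),
    not reports.  PTs without a SOC mapping aggregate into an explicit
    "unmapped" row.  SOCs with zero events are omitted.
    """
    soc_counts: Counter = Counter()
    total = 0
    for r in reports:
        for pt in set(r.events):
            total += 1
            soc = dictionaries.soc_for(pt)
            soc_counts[soc if soc is not None else "unmapped"] += 1
    rows = []
    for soc, count in sorted(soc_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        exact_pct = 100.0 * count / total if total else 0.0
        rows.append(
            {
                "soc": soc,
                "count": count,
                "pct": round_half_up(exact_pct),
                "tier": tier_for(exact_pct),
            }
        )
    return pd.DataFrame(rows, columns=["soc", "count", "pct", "tier"])


def outcome_by_pt(reports: Sequence[Report], top_pts: Sequence[str]) -> pd.DataFrame:
    """PT x outcome-code count matrix over the given PT list.

    A report carrying a PT contributes one count to every outcome code it
    lists; PTs absent from all reports yield zero rows.
    """
    matrix = pd.DataFrame(0, index=list(top_pts), columns=list(OUTCOME_CODES))
    for r in reports:
        pts_here = set(r.events) & set(top_pts)
        for pt in pts_here:
            for code in r.outcomes:
                matrix.loc[pt, code] += 1
    matrix.index.name = "pt"
    return matrix


def frequency_table_to_frame(sections: Mapping[str, Sequence[FrequencyRow]]) -> pd.DataFrame:
    rows = [
        {"section": name, "label": row.label, "count": row.count, "pct": row.pct}
        for name, section in sections.items()
        for row in section
    ]
    return pd.DataFrame(rows, columns=["section", "label", "count", "pct"])
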