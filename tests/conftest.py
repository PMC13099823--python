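"""Shared fixtures: dictionaries, a mid-sized synthetic corpus, and a
case-set fixture reconstructed from printed characteristics-table counts."""

from __future__ import annotations

import itertools

import pytest

from pvsignal._dates import FaersDate
from pvsignal.config import PipelineConfig
from pvsignal.ingest import Report, age_group_for, load_dictionaries
from pvsignal.pipeline import clean_cases, load_input_tables
from pvsignal.synthetic import PlantedSignalSpec, generate_corpus


@pytest.fixture(scope="session")
def dictionaries():
    return load_dictionaries()


@pytest.fixture(scope="session")
def demo_spec():
    return PlantedSignalSpec(n_target_reports=300, n_background_reports=4000, seed=42)


@pytest.fixture(scope="session")
def demo_corpus(demo_spec):
    return generate_corpus(demo_spec)


@pytest.fixture(scope="session")
def demo_populations(demo_spec):
    """(target, background, stage counts) for the session corpus, via the
    full parse/dedup/assembly path."""
    config = PipelineConfig(synthetic=demo_spec)
    tables, deleted = load_input_tables(config)
    return clean_cases(tables, deleted, config)


# ---------------------------------------------------------------------------
# characteristics-table fixture: a 563-report case set whose marginal counts
# equal the printed characteristics of the motivating pralatrexate study.

SEX_COUNTS = {"F": 200, "M": 329, "unknown": 34}
AGE_COUNTS = {"18-44": 52, "45-64": 149, ">=65": 257, "unknown": 105}
YEAR_COUNTS = {
    2009: 6, 2010: 54, 2011: 41, 2012: 36, 2013: 44, 2014: 3, 2015: 25,
    2016: 20, 2017: 13, 2018: 44, 2019: 39, 2020: 37, 2021: 98, 2022: 53,
    2023: 35, 2024: 9, 2025: 6,
}
REPORTER_COUNTS = {
    "consumer": 75, "unknown": 21, "other-health-professional": 138,
    "pharmacist": 77, "physician": 252,
}
COUNTRY_COUNTS = {"US": 234, "JP": 181, "GB": 54, "CO": 37, "BG": 19,
                  "FR": 19, "DE": 19}
OUTCOME_COUNTS = {"LT": 58, "HO": 243, "DS": 10, "DE": 145, "CA": 0,
                  "RI": 1, "OT": 324}
# occurrence-time buckets: representative day counts per printed bucket count
TTO_PLAN = [(16, 192), (45, 49), (75, 21), (105, 12), (135, 8), (165, 7),
            (200, 14), (400, 13)]
# 247 reports without a computable onset, split across exclusion reasons
MISSING_PLAN = {"missing_event_date": 100, "missing_start_date": 100,
                "incomplete_date": 30, "negative": 17}

N_REPORTS = 563


def _expand(counts: dict) -> list:
    return [key for key, n in counts.items() for _ in range(n)]


def build_printed_case_set() -> list[Report]:
    """563 reports whose per-section marginals equal the printed counts.

    Attributes are assigned positionally and independently; outcome codes
    are spread round-robin so that multi-outcome reports exist (their
    patient-level counts sum above the report count).
    """
    sexes = _expand(SEX_COUNTS)
    age_values = _expand({30: 52, 55: 149, 70: 257, None: 105})
    years = _expand(YEAR_COUNTS)
    reporters = _expand(REPORTER_COUNTS)
    countries = _expand(COUNTRY_COUNTS)
    assert len(countries) == N_REPORTS

    outcome_sets: list[set] = [set() for _ in range(N_REPORTS)]
    offset = 0
    for code, count in OUTCOME_COUNTS.items():
        for j in range(count):
            outcome_sets[(offset + j) % N_REPORTS].add(code)
        offset += count

    start = FaersDate(2019, 6, 1)
    onsets: list[tuple] = []  # (therapy_start, event_date)
    for days, count in TTO_PLAN:
        event = FaersDate(*_shift(start, days))
        onsets.extend([(start, event)] * count)
    onsets.extend([(start, None)] * MISSING_PLAN["missing_event_date"])
    onsets.extend([(None, FaersDate(2019, 6, 20))] * MISSING_PLAN["missing_start_date"])
    onsets.extend([(FaersDate(2019, 6), FaersDate(2019, 6, 20))]
                  * MISSING_PLAN["incomplete_date"])
    neg_event = FaersDate(2019, 5, 20)
    onsets.extend([(start, neg_event)] * MISSING_PLAN["negative"])
    assert len(onsets) == N_REPORTS

    reports = []
    for i in range(N_REPORTS):
        age = age_values[i]
        therapy_start, event_date = onsets[i]
        reports.append(
            Report(
                primaryid=str(1000 + i),
                caseid=str(5000 + i),
                fda_dt=FaersDate(years[i], 3, 15),
                sex=sexes[i],
                age_years=None if age is None else float(age),
                age_group=age_group_for(age),
                country=countries[i],
                reporter=reporters[i],
                report_year=years[i],
                outcomes=frozenset(outcome_sets[i]),
                events=("stomatitis",),
                event_date=event_date,
                therapy_start=therapy_start,
            )
        )
    return reports


def _shift(start: FaersDate, days: int) -> tuple[int, int, int]:
    import datetime as dt

    d = start.to_date() + dt.timedelta(days=days)
    return d.year, d.month, d.day


@pytest.fixture(scope="session")
def printed_case_set():
    return build_printed_case_set()
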