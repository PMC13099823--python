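"""Synthetic FAERS-shaped corpora with planted drug-event associations.

Emits quarterly DEMO/DRUG/REAC/OUTC/THER/INDI/RPSR tables in the exact
``$``-delimited ASCII dialect the ingest module reads, together with a
deleted-case list and a ground-truth sidecar, so that every downstream
stage (deduplication, target screening, disproportionality, time-to-onset,
subgroups) can be exercised and validated without the multi-gigabyte FAERS
download.

The generative model, per report:

* the target drug's reports carry each planted PT with probability
  min(1, rr * baseline); background reports with probability ``baseline``
  (so rr is the planted relative reporting risk);
* a pool of null background PTs is sampled identically in both
  populations; reports that sample no event draw one PT from that pool
  (FAERS reports always list at least one reaction);
* onset: event_date - therapy_start ~ Weibull(scale, shape), rounded to
  whole days; a configurable fraction of reports lose one date, and a
  small fraction get an event date before therapy start (contamination
  the time-to-onset filter must remove);
* a fraction of cases is emitted twice under the same CASEID with a
  different PRIMARYID and earlier-or-equal FDA_DT (the duplicates the
  deduplication rule must drop), and a fraction of CASEIDs goes on the
  deleted-case list.

Default parameters mirror the demographic mix, onset-time distribution and
report volume of the motivating pralatrexate case study (563 target
reports; Weibull scale 45.74 days, shape 0.63; ~44% of reports without a
computable onset).
"""

from __future__ import annotations

import datetime as dt
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ingest import RawRecordSet, TABLE_IDS, merge_record_sets, parse_table

_BASE_DATE = dt.date(2009, 1, 1)
_END_DATE = dt.date(2025, 3, 31)

DEMO_COLUMNS = [
    "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
    "sex", "age", "age_cod", "occp_cod", "occr_country",
]
TABLE_COLUMNS = {
    "DEMO": DEMO_COLUMNS,
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    "RPSR": ["primaryid", "caseid", "rpsr_cod"],
}

_TARGET_RAW_NAMES = ("FOLOTYN", "Pralatrexate", "PRALATREXATE INJECTION")
_BACKGROUND_DRUGS = (
    "TREXALL", "ISTODAX", "BELEODAQ", "ADCETRIS", "REVLIMID",
    "RITUXAN", "GEMZAR", "TREANDA", "ONCOVIN", "ADRIAMYCIN",
)
_REPORTER_TO_CODE = {
    "physician": "MD",
    "pharmacist": "PH",
    "other-health-professional": "HP",
    "consumer": "CN",
    "unknown": "",
}
_RPSR_CODES = ("FRGN", "HP", "CSM", "LIT", "OTH")
_INDICATIONS = (
    "peripheral t-cell lymphoma", "rheumatoid arthritis",
    "non-hodgkin lymphoma", "multiple myeloma", "breast cancer",
)


@dataclass(frozen=True)
class PlantedAssociation:
    """One planted drug-event association.

    ``rr`` is the true relative reporting risk of the PT under the target
    drug; ``baseline`` the background per-report carry probability.  If
    ``sex`` is "F" or "M", only target reports of that sex get the elevated
    risk (for planted sex-specific signals).
    """

    pt: str
    rr: float
    baseline: float
    sex: Optional[str] = None


def _default_associations() -> list[PlantedAssociation]:
    # Planted signal profile loosely shaped like an antifolate's: mucosal,
    # hematologic, hepatic and dermatologic toxicity plus a few rare terms.
    raw = [
        ("stomatitis", 40, 0.005), ("mucosal inflammation", 40, 0.004),
        ("platelet count decreased", 30, 0.006),
        ("neutrophil count decreased", 30, 0.005),
        ("anaemia", 8, 0.02), ("neutropenia", 10, 0.015),
        ("thrombocytopenia", 12, 0.012),
        ("toxic epidermal necrolysis", 15, 0.002),
        ("tumour lysis syndrome", 20, 0.002),
        ("malignant neoplasm progression", 10, 0.01),
        ("alanine aminotransferase increased", 6, 0.01),
        ("aspartate aminotransferase increased", 6, 0.01),
        ("intestinal ischaemia", 12, 0.001),
        ("activated partial thromboplastin time prolonged", 10, 0.0015),
        ("platelet count increased", 8, 0.002),
        ("blood chloride decreased", 10, 0.001),
        ("small intestinal perforation", 10, 0.001),
        ("sepsis", 5, 0.008), ("pyrexia", 6, 0.02), ("epistaxis", 8, 0.004),
    ]
    return [PlantedAssociation(pt, float(rr), p) for pt, rr, p in raw]


def _default_background_pts() -> list[tuple[str, float]]:
    return [
        ("nausea", 0.06), ("headache", 0.05), ("diarrhoea", 0.05),
        ("fatigue", 0.05), ("vomiting", 0.04), ("dizziness", 0.03),
        ("rash", 0.03), ("dyspnoea", 0.03), ("pain", 0.03),
        ("pruritus", 0.02), ("arthralgia", 0.02), ("insomnia", 0.02),
        ("constipation", 0.02), ("cough", 0.02), ("oedema peripheral", 0.02),
        ("hypertension", 0.02), ("abdominal pain", 0.02),
        ("decreased appetite", 0.02), ("back pain", 0.02), ("malaise", 0.02),
        ("anxiety", 0.015), ("chest pain", 0.015), ("weight decreased", 0.015),
        ("myalgia", 0.015), ("alopecia", 0.015), ("urticaria", 0.01),
        ("somnolence", 0.01), ("tremor", 0.01), ("palpitations", 0.01),
        ("dry mouth", 0.01),
    ]


def _default_demographics() -> dict[str, dict[str, float]]:
    # Proportions of the motivating case study's characteristics table
    # (563 reports), expressed as exact count fractions.
    n = 563.0
    return {
        "sex": {"F": 200 / n, "M": 329 / n, "unknown": 34 / n},
        "age_group": {"18-44": 52 / n, "45-64": 149 / n, ">=65": 257 / n,
                      "unknown": 105 / n},
        "country": {"US": 234 / n, "JP": 181 / n, "GB": 54 / n, "CO": 37 / n,
                    "BG": 19 / n, "OTHER": 38 / n},
        "reporter": {"physician": 252 / n, "other-health-professional": 138 / n,
                     "pharmacist": 77 / n, "consumer": 75 / n, "unknown": 21 / n},
        # relative frequencies of the first outcome code drawn per report
        "outcomes": {"OT": 324 / 781, "HO": 243 / 781, "DE": 145 / 781,
                     "LT": 58 / 781, "DS": 10 / 781, "RI": 1 / 781, "CA": 0.0},
    }


@dataclass
class PlantedSignalSpec:
    """Ground-truth description of a synthetic corpus."""

    target_drug: str = "pralatrexate"
    associations: list[PlantedAssociation] = field(default_factory=_default_associations)
    background_pts: list[tuple[str, float]] = field(default_factory=_default_background_pts)
    n_target_reports: int = 563
    n_background_reports: int = 20_000
    duplicate_fraction: float = 0.10
    deleted_fraction: float = 0.02
    tto_scale: float = 45.74
    tto_shape: float = 0.63
    missing_date_fraction: float = 0.44
    negative_date_fraction: float = 0.02
    secondary_outcome_rate: float = 0.39
    demographic_mix: dict[str, dict[str, float]] = field(default_factory=_default_demographics)
    seed: int = 0

    def validate(self) -> None:
        if self.n_target_reports <= 0 or self.n_background_reports <= 0:
            raise ValueError("report counts must be positive")
        for frac_name in ("duplicate_fraction", "deleted_fraction",
                          "missing_date_fraction", "negative_date_fraction",
                          "secondary_outcome_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.tto_scale <= 0 or self.tto_shape <= 0:
            raise ValueError("Weibull onset parameters must be positive")
        for assoc in self.associations:
            if assoc.rr < 0:
                raise ValueError(f"relative risk must be >= 0 for {assoc.pt!r}")
            if not 0.0 <= assoc.baseline <= 1.0:
                raise ValueError(f"baseline out of [0,1] for {assoc.pt!r}")
            if assoc.sex not in (None, "F", "M"):
                raise ValueError(f"sex restriction must be F/M/None for {assoc.pt!r}")
        for pt, p in self.background_pts:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background baseline out of [0,1] for {pt!r}")
        if not self.background_pts:
            raise ValueError("background PT pool must not be empty")
        for name, mix in self.demographic_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"demographic mix {name!r} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"demographic mix {name!r} has negative mass")


@dataclass
class SyntheticCorpus:
    """In-memory corpus: per-quarter per-table rows, deletions, ground truth."""

    quarters: dict[str, dict[str, list[dict]]]
    deleted_caseids: list[str]
    ground_truth: dict

    def to_streams(self) -> dict[str, dict[str, io.StringIO]]:
        """Render the exact ASCII dialect, one stream per quarter and table."""
        out: dict[str, dict[str, io.StringIO]] = {}
        for quarter in sorted(self.quarters):
            out[quarter] = {}
            for table_id in TABLE_IDS:
                rows = self.quarters[quarter].get(table_id, [])
                cols = TABLE_COLUMNS[table_id]
                buf = io.StringIO()
                buf.write("$".join(cols) + "\n")
                for row in rows:
                    buf.write("$".join(str(row.get(c, "")) for c in cols) + "\n")
                buf.seek(0)
                out[quarter][table_id] = buf
        return out

    def to_record_sets(self) -> dict[str, RawRecordSet]:
        """Parse the rendered dialect and merge tables across quarters."""
        per_table: dict[str, list[RawRecordSet]] = {t: [] for t in TABLE_IDS}
        for quarter, streams in self.to_streams().items():
            for table_id, stream in streams.items():
                per_table[table_id].append(parse_table(stream, table_id, quarter))
        return {t: merge_record_sets(sets) for t, sets in per_table.items()}

    def write(self, outdir: str | Path) -> None:
        """Write quarterly ASCII files, the deleted-case list and the
        ground-truth sidecar (tests must not read the sidecar through the
        pipeline path)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for quarter, streams in self.to_streams().items():
            qdir = outdir / quarter
            qdir.mkdir(exist_ok=True)
            for table_id, stream in streams.items():
                (qdir / f"{table_id}{quarter}.txt").write_text(
                    stream.getvalue(), encoding="utf-8"
                )
        (outdir / "deleted_caseids.txt").write_text(
            "".join(f"{c}\n" for c in self.deleted_caseids), encoding="utf-8"
        )
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=1, sort_keys=True), encoding="utf-8"
        )


def _choice(rng: np.random.Generator, mix: dict[str, float], size: int) -> list[str]:
    labels = list(mix)
    p = np.asarray([mix[k] for k in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=size, p=p)
    return [labels[i] for i in idx]


def _quarter_of(d: dt.date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


_AGE_RANGES = {"<18": (2, 18), "18-44": (18, 45), "45-64": (45, 65), ">=65": (65, 90)}


def generate_corpus(spec: PlantedSignalSpec) -> SyntheticCorpus:
    """Generate a corpus under ``spec``; byte-identical for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_t, n_b = spec.n_target_reports, spec.n_background_reports
    n = n_t + n_b
    is_target = np.arange(n) < n_t

    horizon = (_END_DATE - _BASE_DATE).days
    fda_off = rng.integers(0, horizon + 1, size=n)

    mix = spec.demographic_mix
    sexes = _choice(rng, mix["sex"], n)
    age_groups = _choice(rng, mix["age_group"], n)
    countries = _choice(rng, mix["country"], n)
    reporters = _choice(rng, mix["reporter"], n)

    age_years = np.full(n, -1, dtype=int)
    for i, g in enumerate(age_groups):
        if g == "unknown":
            continue
        lo, hi = _AGE_RANGES[g]
        age_years[i] = rng.integers(lo, hi)
    age_in_months = rng.random(n) < 0.05  # exercise the AGE_COD conversion

    first_outcome = _choice(rng, mix["outcomes"], n)
    has_second = rng.random(n) < spec.secondary_outcome_rate
    second_outcome = _choice(rng, mix["outcomes"], n)

    # --- events -------------------------------------------------------
    carriers: list[tuple[str, np.ndarray]] = []
    sex_arr = np.asarray(sexes)
    for assoc in spec.associations:
        prob = np.full(n, assoc.baseline)
        elevated = is_target.copy()
        if assoc.sex is not None:
            elevated &= sex_arr == assoc.sex
        prob[elevated] = min(1.0, assoc.rr * assoc.baseline)
        carriers.append((assoc.pt, rng.random(n) < prob))
    for pt, p0 in spec.background_pts:
        carriers.append((pt, rng.random(n) < p0))
    fallback = rng.integers(0, len(spec.background_pts), size=n)

    # --- onset dates --------------------------------------------------
    tto_days = np.rint(spec.tto_scale * rng.weibull(spec.tto_shape, size=n)).astype(int)
    report_lag = rng.integers(0, 61, size=n)
    neg_mask = rng.random(n) < spec.negative_date_fraction
    neg_offset = rng.integers(1, 31, size=n)
    miss_mask = rng.random(n) < spec.missing_date_fraction
    miss_event = rng.random(n) < 0.5  # which date to strip when missing

    # --- contamination ------------------------------------------------
    n_dup = int(round(spec.duplicate_fraction * n))
    dup_idx = set(rng.choice(n, size=n_dup, replace=False).tolist()) if n_dup else set()
    dup_same_dt = rng.random(n) < 0.2
    dup_back = rng.integers(30, 201, size=n)
    n_del = int(round(spec.deleted_fraction * n))
    del_idx = set(rng.choice(n, size=n_del, replace=False).tolist()) if n_del else set()

    con_mask = rng.random(n) < 0.3
    con_choice = rng.integers(0, len(_BACKGROUND_DRUGS), size=n)
    target_as_con = rng.random(n) < 0.02  # target drug concomitant in background
    bg_ps_choice = rng.integers(0, len(_BACKGROUND_DRUGS), size=n)
    bg_unmapped = rng.random(n) < 0.01  # PS name absent from the synonym table
    rpsr_choice = rng.integers(0, len(_RPSR_CODES), size=n)
    indi_choice = rng.integers(1, len(_INDICATIONS), size=n)

    quarters: dict[str, dict[str, list[dict]]] = {}

    def rows_for(quarter: str, table_id: str) -> list[dict]:
        return quarters.setdefault(quarter, {t: [] for t in TABLE_IDS})[table_id]

    deleted_caseids: list[str] = []
    gt_target_carriers: dict[str, int] = {}
    gt_background_carriers: dict[str, int] = {}
    n_complete_tto_target = 0

    for i in range(n):
        caseid = 10_000_000 + i
        duplicated = i in dup_idx
        version = 2 if duplicated else 1
        primaryid = caseid * 10 + version
        fda = _BASE_DATE + dt.timedelta(days=int(fda_off[i]))

        events = [pt for pt, mask in carriers if mask[i]]
        if not events:
            events = [spec.background_pts[fallback[i]][0]]

        start = fda - dt.timedelta(days=int(report_lag[i]) + max(int(tto_days[i]), 0))
        if neg_mask[i]:
            event_date = start - dt.timedelta(days=int(neg_offset[i]))
        else:
            event_date = start + dt.timedelta(days=int(tto_days[i]))
        start_str = start.strftime("%Y%m%d")
        event_str = event_date.strftime("%Y%m%d")
        if miss_mask[i]:
            if miss_event[i]:
                event_str = ""
            else:
                start_str = ""

        if age_years[i] < 0:
            age_str, age_cod = "", ""
        elif age_in_months[i]:
            age_str, age_cod = str(age_years[i] * 12), "MON"
        else:
            age_str, age_cod = str(age_years[i]), "YR"

        sex_str = "" if sexes[i] == "unknown" else sexes[i]
        country = countries[i]
        outcodes = [first_outcome[i]]
        if has_second[i] and second_outcome[i] != first_outcome[i]:
            outcodes.append(second_outcome[i])

        if is_target[i]:
            ps_name = _TARGET_RAW_NAMES[i % len(_TARGET_RAW_NAMES)]
            indication = _INDICATIONS[0]
        else:
            if bg_unmapped[i]:
                ps_name = "CHOP REGIMEN"
            else:
                ps_name = _BACKGROUND_DRUGS[bg_ps_choice[i]]
            indication = _INDICATIONS[indi_choice[i]]

        for pt in events:
            if is_target[i]:
                gt_target_carriers[pt] = gt_target_carriers.get(pt, 0) + 1
            else:
                gt_background_carriers[pt] = gt_background_carriers.get(pt, 0) + 1
        if is_target[i] and not miss_mask[i] and not neg_mask[i]:
            n_complete_tto_target += 1

        versions = [(primaryid, version, fda)]
        if duplicated:
            if dup_same_dt[i]:
                dup_fda = fda
            else:
                dup_fda = fda - dt.timedelta(days=int(dup_back[i]))
            versions.append((caseid * 10 + 1, 1, dup_fda))

        for pid, ver, ver_fda in versions:
            quarter = _quarter_of(ver_fda)
            rows_for(quarter, "DEMO").append({
                "primaryid": pid, "caseid": caseid, "caseversion": ver,
                "fda_dt": ver_fda.strftime("%Y%m%d"), "event_dt": event_str,
                "sex": sex_str, "age": age_str, "age_cod": age_cod,
                "occp_cod": _REPORTER_TO_CODE[reporters[i]],
                "occr_country": country,
            })
            drug_rows = rows_for(quarter, "DRUG")
            drug_rows.append({
                "primaryid": pid, "caseid": caseid, "drug_seq": 1,
                "role_cod": "PS", "drugname": ps_name,
            })
            if con_mask[i]:
                if not is_target[i] and target_as_con[i]:
                    con_name = _TARGET_RAW_NAMES[0]
                else:
                    con_name = _BACKGROUND_DRUGS[con_choice[i]]
                drug_rows.append({
                    "primaryid": pid, "caseid": caseid, "drug_seq": 2,
                    "role_cod": "C", "drugname": con_name,
                })
            for pt in events:
                rows_for(quarter, "REAC").append(
                    {"primaryid": pid, "caseid": caseid, "pt": pt}
                )
            for code in outcodes:
                rows_for(quarter, "OUTC").append(
                    {"primaryid": pid, "caseid": caseid, "outc_cod": code}
                )
            if start_str:
                rows_for(quarter, "THER").append({
                    "primaryid": pid, "caseid": caseid, "dsg_drug_seq": 1,
                    "start_dt": start_str, "end_dt": "",
                })
            rows_for(quarter, "INDI").append({
                "primaryid": pid, "caseid": caseid, "indi_drug_seq": 1,
                "indi_pt": indication,
            })
            rows_for(quarter, "RPSR").append({
                "primaryid": pid, "caseid": caseid,
                "rpsr_cod": _RPSR_CODES[rpsr_choice[i]],
            })

        if i in del_idx:
            deleted_caseids.append(str(caseid))

    ground_truth = {
        "target_drug": spec.target_drug,
        "n_target_reports": n_t,
        "n_background_reports": n_b,
        "n_duplicates_injected": n_dup,
        "n_deleted": n_del,
        "deleted_caseids": sorted(deleted_caseids),
        "tto_scale": spec.tto_scale,
        "tto_shape": spec.tto_shape,
        "n_complete_tto_target": n_complete_tto_target,
        "associations": [
            {
                "pt": a.pt, "rr": a.rr, "baseline": a.baseline, "sex": a.sex,
                "n_target_carriers": gt_target_carriers.get(a.pt, 0),
                "n_background_carriers": gt_background_carriers.get(a.pt, 0),
            }
            for a in spec.associations
        ],
        "seed": spec.seed,
    }
    return SyntheticCorpus(
        quarters=quarters,
        deleted_caseids=deleted_caseids,
        ground_truth=ground_truth,
    )
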