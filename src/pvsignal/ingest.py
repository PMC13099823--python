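"""Parsing and cleaning of FAERS-format quarterly ASCII tables.

The FDA Adverse Event Reporting System publishes each quarter as a set of
``$``-delimited ASCII tables (DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR).
This module parses those tables, removes duplicate case versions (keeping,
per CASEID, the report with the latest FDA receipt date and, on ties, the
largest PRIMARYID), drops cases named on the FDA's deleted-case lists, and
assembles one analysis-ready :class:`Report` per surviving report with
standardized drug names, MedDRA PT lists, outcome codes and onset dates.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from ._dates import FaersDate, parse_faers_date

logger = logging.getLogger(__name__)

TABLE_IDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

#: Outcome codes that make a report "serious" (regulatory convention).
SERIOUS_OUTCOMES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: AGE_COD multipliers to years.  Unknown codes map to missing.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: OCCP_COD -> reporter category (FAERS occupation vocabulary).
REPORTER_MAP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "HP": "other-health-professional",
    "CN": "consumer",
    "LW": "consumer",
}

AGE_GROUPS = ("<18", "18-44", "45-64", ">=65", "unknown")


class ParseError(ValueError):
    """Raised when a FAERS table stream violates the format contract."""


@dataclass
class RawRecordSet:
    """Rows of one FAERS table for one quarter, as string maps.

    Column names are lower-cased; unknown columns are preserved verbatim.
    Every row is guaranteed to carry a non-empty ``primaryid``.
    """

    table_id: str
    quarter: str
    rows: list[dict]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DedupResult:
    kept: RawRecordSet
    rejects: list[dict]
    n_removed: int


@dataclass
class DictionaryTables:
    """PT -> primary SOC map and raw drug-name -> generic-name synonyms.

    Lookups are case-insensitive after whitespace normalization.
    """

    pt_to_soc: Mapping[str, str]
    drug_synonyms: Mapping[str, str]

    def __post_init__(self) -> None:
        self.pt_to_soc = {_norm(k): _norm(v) for k, v in self.pt_to_soc.items()}
        self.drug_synonyms = {_norm(k): _norm(v) for k, v in self.drug_synonyms.items()}

    def soc_for(self, pt: str) -> Optional[str]:
        return self.pt_to_soc.get(_norm(pt))

    def standardize_drug(self, raw: str) -> tuple[str, bool]:
        """Return (generic name, mapped?).  Unmapped names pass verbatim."""
        key = _norm(raw)
        if key in self.drug_synonyms:
            return self.drug_synonyms[key], True
        return key, False


@dataclass(frozen=True)
class DrugEntry:
    name: str
    role: str  # PS / SS / C / I
    start_date: Optional[FaersDate] = None
    mapped: bool = True


@dataclass
class Report:
    """One deduplicated FAERS case — the unit of every downstream analysis."""

    primaryid: str
    caseid: str
    fda_dt: Optional[FaersDate]
    sex: str  # "F" / "M" / "unknown"
    age_years: Optional[float]
    age_group: str
    country: str
    reporter: str
    report_year: Optional[int]
    outcomes: frozenset
    drugs: tuple = ()
    events: tuple = ()  # unique PTs, lower-cased
    event_date: Optional[FaersDate] = None
    therapy_start: Optional[FaersDate] = None

    @property
    def serious(self) -> bool:
        return bool(self.outcomes & SERIOUS_OUTCOMES)

    def ps_drug(self) -> Optional[str]:
        for d in self.drugs:
            if d.role == "PS":
                return d.name
        return None


def _norm(s: str) -> str:
    return " ".join(s.split()).lower()


def age_group_for(age_years: Optional[float]) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


# ---------------------------------------------------------------------------
# parsing


def parse_table(
    stream: Union[str, Path, TextIO],
    table_id: str,
    quarter: str = "",
    delimiter: str = "$",
) -> RawRecordSet:
    """Parse one ``$``-delimited FAERS table with a header line.

    The header must name a PRIMARYID column; each data line must have the
    header's field count.  Unknown columns are preserved.
    """
    if table_id not in TABLE_IDS:
        raise ParseError(f"unknown FAERS table id {table_id!r}")
    if isinstance(stream, (str, Path)):
        with open(stream, "r", encoding="utf-8") as fh:
            return parse_table(fh, table_id, quarter, delimiter)

    reader = csv.reader(stream, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{table_id}: empty stream, no header line") from None
    columns = [c.strip().lower() for c in header]
    if "primaryid" not in columns:
        raise ParseError(f"{table_id}: mandatory column PRIMARYID missing from header")

    rows: list[dict] = []
    for lineno, fields in enumerate(reader, start=2):
        if not fields:
            continue
        if len(fields) != len(columns):
            raise ParseError(
                f"{table_id} line {lineno}: expected {len(columns)} fields, "
                f"got {len(fields)}"
            )
        row = dict(zip(columns, (f.strip() for f in fields)))
        if not row.get("primaryid"):
            raise ParseError(f"{table_id} line {lineno}: empty PRIMARYID")
        rows.append(row)
    return RawRecordSet(table_id=table_id, quarter=quarter, rows=rows)


def parse_quarter(
    files: Mapping[str, Union[str, Path, TextIO]],
    quarter: str = "",
    delimiter: str = "$",
) -> dict[str, RawRecordSet]:
    """Parse all provided per-table streams of one quarterly archive."""
    out = {}
    for table_id, stream in files.items():
        out[table_id] = parse_table(stream, table_id, quarter, delimiter)
    return out


def merge_record_sets(sets: Iterable[RawRecordSet]) -> RawRecordSet:
    """Concatenate the same table across quarters."""
    sets = list(sets)
    if not sets:
        raise ValueError("nothing to merge")
    table_ids = {s.table_id for s in sets}
    if len(table_ids) != 1:
        raise ValueError(f"cannot merge different tables: {sorted(table_ids)}")
    rows = [r for s in sets for r in s.rows]
    quarters = ",".join(dict.fromkeys(s.quarter for s in sets))
    return RawRecordSet(table_id=sets[0].table_id, quarter=quarters, rows=rows)


# ---------------------------------------------------------------------------
# cleaning


def _pid_key(pid: str):
    # FAERS PRIMARYIDs are numeric; compare numerically, falling back to text.
    return (0, int(pid), "") if pid.isdigit() else (1, 0, pid)


def deduplicate(demo: RawRecordSet) -> DedupResult:
    """Keep one DEMO row per CASEID: latest FDA_DT, then largest PRIMARYID.

    Rows with an unparseable FDA_DT or missing CASEID are quarantined into
    the rejects list rather than silently dropped.  Output is sorted by
    (CASEID, FDA_DT, PRIMARYID).
    """
    best: dict[str, tuple] = {}
    rejects: list[dict] = []
    n_valid = 0
    for row in demo.rows:
        caseid = row.get("caseid", "").strip()
        if not caseid:
            rejects.append({**row, "_reject_reason": "missing_caseid"})
            continue
        try:
            fda = parse_faers_date(row.get("fda_dt"))
        except ValueError:
            rejects.append({**row, "_reject_reason": "unparseable_fda_dt"})
            continue
        if fda is None:
            rejects.append({**row, "_reject_reason": "missing_fda_dt"})
            continue
        n_valid += 1
        key = (fda.as_int(), _pid_key(row["primaryid"]))
        if caseid not in best or key > best[caseid][0]:
            best[caseid] = (key, row)

    kept_rows = [row for _, row in best.values()]
    kept_rows.sort(
        key=lambda r: (r["caseid"], parse_faers_date(r["fda_dt"]).as_int(), _pid_key(r["primaryid"]))
    )
    n_removed = n_valid - len(kept_rows)
    if rejects:
        logger.warning("deduplicate: quarantined %d DEMO rows", len(rejects))
    logger.info(
        "deduplicate: %d rows -> %d cases (%d duplicate versions removed)",
        len(demo.rows), len(kept_rows), n_removed,
    )
    return DedupResult(
        kept=RawRecordSet(demo.table_id, demo.quarter, kept_rows),
        rejects=rejects,
        n_removed=n_removed,
    )


def remove_deleted(
    demo: RawRecordSet, deleted_caseids: Iterable[str]
) -> tuple[RawRecordSet, int]:
    """Drop rows whose CASEID appears on the FDA deleted-case list."""
    deleted = {str(c).strip() for c in deleted_caseids if str(c).strip()}
    kept = [r for r in demo.rows if r.get("caseid", "").strip() not in deleted]
    n_removed = len(demo.rows) - len(kept)
    logger.info("remove_deleted: removed %d of %d rows", n_removed, len(demo.rows))
    if demo.rows and not kept:
        logger.warning("remove_deleted: deleted list removed every case")
    return RawRecordSet(demo.table_id, demo.quarter, kept), n_removed


def read_deleted_list(stream: Union[str, Path, TextIO]) -> list[str]:
    """One CASEID per line; blank lines ignored."""
    if isinstance(stream, (str, Path)):
        with open(stream, "r", encoding="utf-8") as fh:
            return read_deleted_list(fh)
    return [line.strip() for line in stream if line.strip()]


# ---------------------------------------------------------------------------
# case assembly


def _age_to_years(age_raw: str, unit_raw: str) -> Optional[float]:
    age_raw = age_raw.strip()
    if not age_raw:
        return None
    try:
        age = float(age_raw)
    except ValueError:
        return None
    factor = AGE_UNIT_TO_YEARS.get(unit_raw.strip().upper())
    if factor is None:
        return None
    years = age * factor
    return years if years >= 0 else None


def _safe_date(raw: Optional[str]) -> Optional[FaersDate]:
    try:
        return parse_faers_date(raw)
    except ValueError:
        return None


def assemble_cases(
    tables: Mapping[str, RawRecordSet],
    dictionaries: DictionaryTables,
) -> tuple[list[Report], Counter]:
    """Join the cleaned DEMO table with DRUG/REAC/OUTC/THER into Reports.

    DEMO must already be deduplicated and deletion-filtered.  DRUG/REAC/OUTC
    rows referencing a PRIMARYID absent from DEMO are counted as orphans and
    excluded.  Returns (reports, assembly log counter).
    """
    if "DEMO" not in tables:
        raise ValueError("assemble_cases requires a DEMO table")
    log: Counter = Counter()
    demo_ids = {r["primaryid"] for r in tables["DEMO"].rows}

    # therapy start dates keyed by (primaryid, drug_seq)
    ther_start: dict[tuple[str, str], FaersDate] = {}
    for row in tables.get("THER", RawRecordSet("THER", "", [])).rows:
        pid = row["primaryid"]
        if pid not in demo_ids:
            log["orphan_THER"] += 1
            continue
        d = _safe_date(row.get("start_dt"))
        if d is None:
            continue
        key = (pid, row.get("dsg_drug_seq", "").strip())
        if key not in ther_start or d.as_int() < ther_start[key].as_int():
            ther_start[key] = d

    drugs_by_pid: dict[str, list[DrugEntry]] = {}
    for row in tables.get("DRUG", RawRecordSet("DRUG", "", [])).rows:
        pid = row["primaryid"]
        if pid not in demo_ids:
            log["orphan_DRUG"] += 1
            continue
        name, mapped = dictionaries.standardize_drug(row.get("drugname", ""))
        if not mapped:
            log["unmapped_drug_name"] += 1
        seq = row.get("drug_seq", "").strip()
        entry = DrugEntry(
            name=name,
            role=row.get("role_cod", "").strip().upper(),
            start_date=ther_start.get((pid, seq)),
            mapped=mapped,
        )
        drugs_by_pid.setdefault(pid, []).append(entry)

    events_by_pid: dict[str, dict[str, None]] = {}
    for row in tables.get("REAC", RawRecordSet("REAC", "", [])).rows:
        pid = row["primaryid"]
        if pid not in demo_ids:
            log["orphan_REAC"] += 1
            continue
        pt = _norm(row.get("pt", ""))
        if not pt:
            log["blank_pt"] += 1
            continue
        # identical PTs within one report collapse to one occurrence
        events_by_pid.setdefault(pid, {})[pt] = None

    outcomes_by_pid: dict[str, set] = {}
    for row in tables.get("OUTC", RawRecordSet("OUTC", "", [])).rows:
        pid = row["primaryid"]
        if pid not in demo_ids:
            log["orphan_OUTC"] += 1
            continue
        code = row.get("outc_cod", "").strip().upper()
        if code in OUTCOME_CODES:
            outcomes_by_pid.setdefault(pid, set()).add(code)

    reports: list[Report] = []
    for row in tables["DEMO"].rows:
        pid = row["primaryid"]
        fda = _safe_date(row.get("fda_dt"))
        sex = row.get("sex", "").strip().upper()
        if sex not in ("F", "M"):
            sex = "unknown"
        age_years = _age_to_years(row.get("age", ""), row.get("age_cod", "YR"))
        drugs = tuple(drugs_by_pid.get(pid, ()))
        # therapy start: earliest start date across PS-drug rows
        ps_starts = [d.start_date for d in drugs if d.role == "PS" and d.start_date]
        therapy_start = min(ps_starts, key=lambda d: d.as_int()) if ps_starts else None
        occp = row.get("occp_cod", "").strip().upper()
        reports.append(
            Report(
                primaryid=pid,
                caseid=row.get("caseid", "").strip(),
                fda_dt=fda,
                sex=sex,
                age_years=age_years,
                age_group=age_group_for(age_years),
                country=row.get("occr_country", row.get("country", "")).strip(),
                reporter=REPORTER_MAP.get(occp, "unknown"),
                report_year=fda.year if fda else None,
                outcomes=frozenset(outcomes_by_pid.get(pid, set())),
                drugs=drugs,
                events=tuple(events_by_pid.get(pid, {})),
                event_date=_safe_date(row.get("event_dt")),
                therapy_start=therapy_start,
            )
        )
    log["reports"] = len(reports)
    return reports, log


def select_target_population(
    reports: Sequence[Report], target_drug: str
) -> tuple[list[Report], list[Report]]:
    """Partition reports by whether the primary-suspect drug is the target.

    Reports with no PS-role drug go to the background (and are counted in
    the log).  The partition is exhaustive and disjoint.
    """
    target_key = _norm(target_drug)
    target: list[Report] = []
    background: list[Report] = []
    n_no_ps = 0
    for r in reports:
        ps = r.ps_drug()
        if ps is None:
            n_no_ps += 1
            background.append(r)
        elif _norm(ps) == target_key:
            target.append(r)
        else:
            background.append(r)
    if n_no_ps:
        logger.info("select_target_population: %d reports with no PS drug", n_no_ps)
    return target, background


# ---------------------------------------------------------------------------
# tabular export round-trip

_EXPORT_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "sex", "age_years", "age_group",
    "country", "reporter", "report_year", "outcomes", "drugs", "events",
    "event_date", "therapy_start",
]


def _fmt_date(d: Optional[FaersDate]) -> str:
    return str(d) if d is not None else ""


def write_cases(reports: Sequence[Report], stream: Union[str, Path, TextIO]) -> None:
    """Write the cleaned case set as a tab-delimited table (documented contract).

    Multi-valued fields are packed: outcomes as comma-joined codes, drugs as
    ``name|role|start_date`` triples joined by ``;``, events comma-joined.
    """
    if isinstance(stream, (str, Path)):
        with open(stream, "w", encoding="utf-8", newline="") as fh:
            write_cases(reports, fh)
        return
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_EXPORT_COLUMNS)
    for r in reports:
        writer.writerow([
            r.primaryid,
            r.caseid,
            _fmt_date(r.fda_dt),
            r.sex,
            "" if r.age_years is None else repr(r.age_years),
            r.age_group,
            r.country,
            r.reporter,
            "" if r.report_year is None else r.report_year,
            ",".join(sorted(r.outcomes)),
            ";".join(f"{d.name}|{d.role}|{_fmt_date(d.start_date)}|{int(d.mapped)}" for d in r.drugs),
            ",".join(r.events),
            _fmt_date(r.event_date),
            _fmt_date(r.therapy_start),
        ])


def read_cases(stream: Union[str, Path, TextIO]) -> list[Report]:
    """Inverse of :func:`write_cases`."""
    if isinstance(stream, (str, Path)):
        with open(stream, "r", encoding="utf-8") as fh:
            return read_cases(fh)
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader)
    if header != _EXPORT_COLUMNS:
        raise ParseError("case-set table has an unexpected column contract")
    out: list[Report] = []
    for row in reader:
        rec = dict(zip(header, row))
        drugs = []
        if rec["drugs"]:
            for item in rec["drugs"].split(";"):
                name, role, start, mapped = item.split("|")
                drugs.append(DrugEntry(name, role, _safe_date(start), bool(int(mapped))))
        out.append(
            Report(
                primaryid=rec["primaryid"],
                caseid=rec["caseid"],
                fda_dt=_safe_date(rec["fda_dt"]),
                sex=rec["sex"],
                age_years=float(rec["age_years"]) if rec["age_years"] else None,
                age_group=rec["age_group"],
                country=rec["country"],
                reporter=rec["reporter"],
                report_year=int(rec["report_year"]) if rec["report_year"] else None,
                outcomes=frozenset(rec["outcomes"].split(",")) if rec["outcomes"] else frozenset(),
                drugs=tuple(drugs),
                events=tuple(rec["events"].split(",")) if rec["events"] else (),
                event_date=_safe_date(rec["event_date"]),
                therapy_start=_safe_date(rec["therapy_start"]),
            )
        )
    return out


def load_dictionaries(
    pt_to_soc_path: Union[str, Path, TextIO, None] = None,
    drug_synonyms_path: Union[str, Path, TextIO, None] = None,
) -> DictionaryTables:
    """Load the PT->SOC and drug-synonym TSVs; defaults to the bundled mock
    dictionary (real MedDRA is license-gated)."""
    from importlib import resources

    def _read_tsv(src, default_name):
        if src is None:
            src = io.StringIO(
                resources.files("pvsignal.data").joinpath(default_name).read_text("utf-8")
            )
        if isinstance(src, (str, Path)):
            with open(src, "r", encoding="utf-8") as fh:
                return _read_tsv(fh, default_name)
        mapping = {}
        for line in src:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("\t")
            mapping[key] = value
        return mapping

    return DictionaryTables(
        pt_to_soc=_read_tsv(pt_to_soc_path, "pt_to_soc.tsv"),
        drug_synonyms=_read_tsv(drug_synonyms_path, "drug_synonyms.tsv"),
    )
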