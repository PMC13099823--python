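"""End-to-end orchestration: ingest -> clean -> signals -> TTO -> subgroups
-> descriptive reports, with a run manifest of counts at every stage.

The manifest makes each run auditable: identical config and seed produce an
identical manifest, and each stage's input count equals the previous
stage's output count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import ingest, reporting, signals, subgroups, tto
from .config import PipelineConfig
from .ingest import RawRecordSet, Report
from .synthetic import generate_corpus
from .subgroups import SubgroupSpec

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """A stage failed on the data it was given."""


def load_input_tables(config: PipelineConfig) -> tuple[dict[str, RawRecordSet], list[str]]:
    """Materialize the raw tables and the deleted-case list from either the
    synthetic generator or a directory of quarterly archives."""
    if config.synthetic is not None:
        corpus = generate_corpus(config.synthetic)
        return corpus.to_record_sets(), list(corpus.deleted_caseids)

    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise DataError(f"input directory {input_dir} does not exist")
    per_table: dict[str, list[RawRecordSet]] = {t: [] for t in ingest.TABLE_IDS}
    for qdir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        quarter = qdir.name
        for table_id in ingest.TABLE_IDS:
            path = qdir / f"{table_id}{quarter}.txt"
            if path.exists():
                per_table[table_id].append(ingest.parse_table(path, table_id, quarter))
    tables = {
        t: ingest.merge_record_sets(sets) for t, sets in per_table.items() if sets
    }
    if "DEMO" not in tables:
        raise DataError(f"no DEMO tables found under {input_dir}")
    deleted_path = Path(config.deleted_list or input_dir / "deleted_caseids.txt")
    deleted = ingest.read_deleted_list(deleted_path) if deleted_path.exists() else []
    return tables, deleted


def clean_cases(
    tables: dict[str, RawRecordSet],
    deleted: list[str],
    config: PipelineConfig,
) -> tuple[list[Report], list[Report], dict]:
    """Dedup + deletion filter + case assembly + target/background split."""
    dictionaries = ingest.load_dictionaries(config.pt_to_soc, config.drug_synonyms)
    dedup = ingest.deduplicate(tables["DEMO"])
    demo_clean, n_deleted = ingest.remove_deleted(dedup.kept, deleted)
    reports, assembly_log = ingest.assemble_cases(
        {**tables, "DEMO": demo_clean}, dictionaries
    )
    target, background = ingest.select_target_population(reports, config.target_drug)
    counts = {
        "demo_rows_parsed": len(tables["DEMO"].rows),
        "demo_rows_quarantined": len(dedup.rejects),
        "duplicates_removed": dedup.n_removed,
        "cases_after_dedup": len(dedup.kept.rows),
        "deleted_removed": n_deleted,
        "cases_after_deletion": len(demo_clean.rows),
        "reports_assembled": len(reports),
        "target_reports": len(target),
        "background_reports": len(background),
        "orphan_rows": sum(v for k, v in assembly_log.items() if k.startswith("orphan_")),
    }
    return target, background, counts


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> dict:
    """Run every stage in order and return the manifest.

    Writes, under the output directory: the cleaned target case set, the
    full signal table, the time-to-onset summary and histogram, per-stratum
    subgroup tables, the sex-difference volcano export, and the descriptive
    tables, plus ``manifest.json``.
    """
    config.validate()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"target_drug": config.target_drug, "stages": {}}

    tables, deleted = load_input_tables(config)
    manifest["stages"]["ingest"] = {
        t: len(rs.rows) for t, rs in sorted(tables.items())
    }

    target, background, clean_counts = clean_cases(tables, deleted, config)
    manifest["stages"]["clean"] = clean_counts
    if not target:
        raise DataError(f"no reports with PS drug {config.target_drug!r}")
    ingest.write_cases(target, outdir / "target_cases.tsv")

    dictionaries = ingest.load_dictionaries(config.pt_to_soc, config.drug_synonyms)
    pt_tables = signals.build_tables(target, background)
    results = signals.detect_signals(pt_tables, config.signal, dictionaries.pt_to_soc)
    frame = signals.signals_to_frame(results)
    frame.to_csv(outdir / "signals.tsv", sep="\t", index=False)
    manifest["stages"]["signals"] = {
        "pts_counted": len(pt_tables),
        "pts_tested": len(results),
        "consensus_signals": int(sum(r.consensus for r in results)),
    }

    records, excluded = tto.compute_tto(target)
    buckets = tto.bucket_distribution(records)
    pd.DataFrame(
        {"bucket": list(buckets), "count": list(buckets.values())}
    ).to_csv(outdir / "tto_buckets.tsv", sep="\t", index=False)
    tto_stage = {
        "included": len(records),
        "excluded": dict(sorted(excluded.items())),
    }
    if len(records) >= 10:
        fit = tto.fit_weibull(records)
        pd.DataFrame([tto.fit_to_row(fit)]).to_csv(
            outdir / "tto_summary.tsv", sep="\t", index=False
        )
        tto_stage["failure_type"] = fit.failure_type
    else:
        logger.warning("too few complete onset intervals for a Weibull fit")
    manifest["stages"]["tto"] = tto_stage

    sub_stage = {}
    strata = [
        SubgroupSpec("sex", "F"), SubgroupSpec("sex", "M"),
        SubgroupSpec("age_group", "18-44"), SubgroupSpec("age_group", "45-64"),
        SubgroupSpec("age_group", ">=65"),
        SubgroupSpec("age_binary", "<65"), SubgroupSpec("age_binary", ">=65"),
        SubgroupSpec("report_type", "serious"),
        SubgroupSpec("report_type", "non-serious"),
    ]
    for spec in strata:
        res = subgroups.stratified_signals(
            target, background, spec, config.signal, dictionaries.pt_to_soc
        )
        label = f"{spec.axis}_{spec.level}".replace("<", "lt").replace(">=", "ge")
        signals.signals_to_frame(res).to_csv(
            outdir / f"subgroup_{label}.tsv", sep="\t", index=False
        )
        sub_stage[f"{spec.axis}:{spec.level}"] = {
            "tested": len(res),
            "ror_signals": int(sum(r.ror_flag for r in res)),
        }
    has_both_sexes = any(r.sex == "F" for r in target) and any(
        r.sex == "M" for r in target
    )
    if has_both_sexes:
        sex_res = subgroups.sex_difference(target)
        subgroups.volcano_frame(sex_res).to_csv(
            outdir / "sex_difference_volcano.tsv", sep="\t", index=False
        )
        sub_stage["sex_difference"] = {
            "tested": len(sex_res),
            "biased": int(sum(r.direction != "none" for r in sex_res)),
        }
    manifest["stages"]["subgroups"] = sub_stage

    sections = reporting.characteristics_table(target)
    reporting.frequency_table_to_frame(sections).to_csv(
        outdir / "characteristics.tsv", sep="\t", index=False
    )
    soc = reporting.soc_distribution(target, dictionaries)
    soc.to_csv(outdir / "soc_distribution.tsv", sep="\t", index=False)
    top_pts = [r.pt for r in results if r.consensus][: config.top_k]
    reporting.outcome_by_pt(target, top_pts).to_csv(
        outdir / "outcome_by_pt.tsv", sep="\t"
    )
    manifest["stages"]["reporting"] = {
        "characteristics_sections": len(sections),
        "soc_rows": len(soc),
        "ae_instances": int(soc["count"].sum()),
        "top_pts": len(top_pts),
    }

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
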