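"""Descriptive tables for the target population: case characteristics,
system-organ-class distribution with frequency tiers, and the outcome
profile of the top consensus signals."""

from common import RESULTS, load_populations, study_config

from pvsignal.ingest import load_dictionaries
from pvsignal.reporting import (
    characteristics_table,
    frequency_table_to_frame,
    outcome_by_pt,
    soc_distribution,
)
from pvsignal.signals import build_tables, detect_signals


def main() -> None:
    config = study_config()
    target, background, _ = load_populations(config)
    dictionaries = load_dictionaries()
    RESULTS.mkdir(parents=True, exist_ok=True)

    sections = characteristics_table(target)
    frequency_table_to_frame(sections).to_csv(
        RESULTS / "characteristics.tsv", sep="\t", index=False
    )
    print(f"characteristics table: {len(target)} reports")
    for row in sections["sex"]:
        print(f"  {row.label:14s} {row.count:4d} ({row.pct:.2f})")

    soc = soc_distribution(target, dictionaries)
    soc.to_csv(RESULTS / "soc_distribution.tsv", sep="\t", index=False)
    n_instances = int(soc["count"].sum())
    print(f"\nSOC distribution over {n_instances} AE instances "
          f"({(soc['tier'] == 'primary').sum()} primary / "
          f"{(soc['tier'] == 'secondary').sum()} secondary / "
          f"{(soc['tier'] == 'rare').sum()} rare):")
    for _, row in soc.head(5).iterrows():
        print(f"  {row['soc'][:52]:52s} {row['count']:4d} ({row['pct']:.2f}%) "
              f"{row['tier']}")

    results = detect_signals(
        build_tables(target, background), config.signal, dictionaries.pt_to_soc
    )
    top_pts = [r.pt for r in results if r.consensus][: config.top_k]
    matrix = outcome_by_pt(target, top_pts)
    matrix.to_csv(RESULTS / "outcome_by_pt.tsv", sep="\t")
    worst = matrix[["DE", "LT", "HO"]].sum(axis=1).sort_values(ascending=False)
    print(f"\noutcome matrix for {len(top_pts)} consensus signals; PTs most "
          f"often tied to death / life-threat / hospitalization:")
    for pt, count in worst.head(3).items():
        print(f"  {pt}: {count} serious-outcome mentions")


if __name__ == "__main__":
    main()
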