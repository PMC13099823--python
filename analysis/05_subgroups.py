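"""Subgroup screening: sex / age / report-seriousness stratified ROR
screens and the female-vs-male per-PT disproportionality test with FDR
adjustment."""

from common import RESULTS, load_populations, study_config

from pvsignal.ingest import load_dictionaries
from pvsignal.signals import signals_to_frame
from pvsignal.subgroups import (
    SubgroupSpec,
    sex_difference,
    stratified_signals,
    volcano_frame,
)


def main() -> None:
    config = study_config()
    target, background, _ = load_populations(config)
    dictionaries = load_dictionaries()
    RESULTS.mkdir(parents=True, exist_ok=True)

    strata = [
        SubgroupSpec("sex", "F"), SubgroupSpec("sex", "M"),
        SubgroupSpec("age_binary", "<65"), SubgroupSpec("age_binary", ">=65"),
        SubgroupSpec("report_type", "serious"),
        SubgroupSpec("report_type", "non-serious"),
    ]
    print("stratified ROR screens (top PTs by report frequency):")
    for spec in strata:
        res = stratified_signals(target, background, spec, config.signal,
                                 dictionaries.pt_to_soc)
        label = f"{spec.axis}_{spec.level}".replace("<", "lt").replace(">=", "ge")
        signals_to_frame(res).to_csv(RESULTS / f"subgroup_{label}.tsv",
                                     sep="\t", index=False)
        hits = [r.pt for r in res if r.ror_flag][:5]
        print(f"  {spec.axis}={spec.level:12s} {sum(r.ror_flag for r in res):3d} "
              f"ROR signals; most frequent: {', '.join(hits) if hits else '-'}")

    sex_res = sex_difference(target)
    volcano_frame(sex_res).to_csv(RESULTS / "sex_difference_volcano.tsv",
                                  sep="\t", index=False)
    biased = [r for r in sex_res if r.direction != "none"]
    print(f"\nsex-difference test over {len(sex_res)} PTs: "
          f"{len(biased)} with a significant direction")
    for r in sorted(biased, key=lambda r: r.p_value)[:5]:
        print(f"  {r.pt}: ROR {r.ror:.2f} "
              f"(95% CI {r.ror_lo:.2f}-{r.ror_hi:.2f}), {r.direction}, "
              f"p={r.p_value:.3g}, q={r.fdr_q:.3g}")


if __name__ == "__main__":
    main()
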