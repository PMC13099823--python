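"""Parse, deduplicate and deletion-filter the study corpus, split it into
the target and background populations, and tabulate the cleaning funnel."""

import pandas as pd

from common import RESULTS, load_populations


def main() -> None:
    target, background, counts = load_populations()
    RESULTS.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(sorted(counts.items()), columns=["stage", "count"])
    frame.to_csv(RESULTS / "cleaning_funnel.tsv", sep="\t", index=False)

    print("cleaning funnel:")
    for stage, count in counts.items():
        print(f"  {stage:24s} {count}")
    print(
        f"\n{counts['duplicates_removed']} duplicate case versions and "
        f"{counts['deleted_removed']} deleted cases were removed; "
        f"{len(target)} target-drug reports remain against a background of "
        f"{len(background)}."
    )


if __name__ == "__main__":
    main()
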