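"""Materialize the study's synthetic FAERS-like corpus as quarterly ASCII
archives (under scratch/, since the rendered corpus is several MB) and
report its composition."""

from common import SCRATCH, study_config

from pvsignal.synthetic import generate_corpus


def main() -> None:
    spec = study_config().synthetic
    corpus = generate_corpus(spec)
    outdir = SCRATCH / "corpus"
    corpus.write(outdir)

    gt = corpus.ground_truth
    n_rows = sum(len(rows) for q in corpus.quarters.values() for rows in q.values())
    print(f"wrote {len(corpus.quarters)} quarterly archives to {outdir}")
    print(f"  total table rows:          {n_rows}")
    print(f"  target reports:            {gt['n_target_reports']}")
    print(f"  background reports:        {gt['n_background_reports']}")
    print(f"  duplicate versions seeded: {gt['n_duplicates_injected']}")
    print(f"  cases on deleted list:     {gt['n_deleted']}")
    print(f"  planted associations:      {len(gt['associations'])}")
    top = max(gt["associations"], key=lambda a: a["rr"])
    print(f"  strongest planted signal:  {top['pt']} (relative risk {top['rr']:g})")


if __name__ == "__main__":
    main()
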