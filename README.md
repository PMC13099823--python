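# pvsignal

Signal detection in spontaneous adverse-event reports, in the style of a
FAERS pharmacovigilance study: standardized report cleaning, four-algorithm
disproportionality analysis with a consensus rule, Weibull time-to-onset
failure typing, and subgroup screening — plus a synthetic FAERS-shaped
corpus generator with planted associations so the whole pipeline can be
developed and validated without the multi-gigabyte FAERS download.

## Who this is for

Pharmacoepidemiologists and biostatisticians who mine the FDA Adverse Event
Reporting System (or similarly shaped spontaneous-report databases) for
drug-safety signals. The package takes the quarterly `$`-delimited ASCII
tables (DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR), cleans them the way
FAERS studies do — one report per CASEID (latest FDA receipt date, largest
PRIMARYID on ties), deleted-case lists honored, drug names standardized
through a synonym table, MedDRA preferred terms (PTs) mapped to a primary
system organ class (SOC) — and screens every PT reported with the target
drug as primary suspect.

## The statistics

For each PT a report-level 2×2 table is built against the rest of the
database (`a` = target drug with the PT, `b` = target drug without, `c`/`d`
the same for all other drugs, `N = a+b+c+d`, `E = (a+b)(a+c)/N`):

| method | statistic | signal threshold |
|---|---|---|
| ROR | `ad/bc`, 95% Wald CI on the log scale | `a ≥ 3` and CI lower bound > 1 |
| PRR (MHRA) | `[a/(a+b)]/[c/(c+d)]`, Yates χ² | `a ≥ 3`, PRR ≥ 2, χ² ≥ 4 |
| BCPNN | IC = log₂ p(drug,event)/p(drug)p(event), Monte-Carlo posterior under the unit-expectation beta priors | IC025 > 0 |
| MGPS | EBGM = 2^E[log₂ λ] with `a ~ Poisson(λE)` under the two-gamma mixture prior (0.2, 0.1, 2.0, 4.0, w=⅓) | EB05 > 2 |

A PT is a **consensus signal** only when all four flags are positive.
Time-to-onset (event date − therapy start, reports with incomplete or
negative intervals excluded and tallied) is fitted by Weibull maximum
likelihood; a shape parameter whose 95% CI lies entirely below 1 indicates
an early-failure pattern — the hazard declines with time on therapy.
Subgroup screens re-run the tables within sex, age and seriousness strata,
and a female-vs-male per-PT ROR with Benjamini–Hochberg FDR adjustment
looks for sex-specific risks.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic corpus (563 target reports vs a 20,000-report background, 10%
duplicated case versions, 2% deleted cases, Weibull(45.74 d, 0.63) onset
times, ~44% of reports with no computable onset):

```bash
cd analysis
python 01_generate_corpus.py   # materialize the quarterly ASCII archives
python 02_clean_cases.py       # dedup -> deletion filter -> target split
python 03_detect_signals.py    # four-algorithm consensus screen
python 04_time_to_onset.py     # Weibull failure-type test
python 05_subgroups.py         # sex/age/seriousness screens
python 06_descriptives.py      # characteristics + SOC tables
```

`02_clean_cases.py` reports the cleaning funnel — 22,619 parsed DEMO rows,
2,056 duplicate versions removed (exactly the number the generator
injected), 411 deleted cases dropped, 551 of the 563 planted target reports
surviving. `03_detect_signals.py` then prints:

```
50 PTs counted, 50 tested (>=3 target reports), 18 consensus signals

top 10 consensus signals by ROR:
                            pt   a   ror  ror_lo   prr    chi2  ic025  eb05
                    stomatitis 106 51.64   38.40 41.90 1942.76   3.70 16.46
          mucosal inflammation  83 40.72   29.69 34.74 1369.87   3.50 14.66
      platelet count decreased  93 32.96   24.76 27.57 1340.42   3.40 13.15
...
18/20 planted associations with relative risk >=5 were recovered as consensus signals
```

and `04_time_to_onset.py` recovers the planted onset distribution:

```
551 target reports -> 325 with a computable onset (226 excluded: ...)
median onset 24 d (IQR 8-80)
Weibull scale 48.96 d (95% CI 41.02-58.43), shape 0.65 (95% CI 0.60-0.71)
failure type: early
```

— the planted scale (45.74) and shape (0.63) sit inside both CIs, and the
shape CI entirely below 1 yields the early-failure call. Output tables land
in `results/tables/`.

The same pipeline is scriptable from a single YAML config via the CLI:

```bash
pvsignal all --config examples/study_config.yaml --out run_out
```

which writes every stage's table plus a `manifest.json` of stage-by-stage
counts (identical for identical config and seed). Real FAERS archives are
analyzed by pointing `input_dir` at a directory of quarterly folders
instead of the `synthetic` block.

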