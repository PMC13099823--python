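# Methods

## Analysis unit and cleaning model

The unit of every analysis is one deduplicated spontaneous report. FAERS
publishes each case possibly many times (follow-up versions across
quarters share a CASEID); the cleaning rule keeps, per CASEID, the row with
the latest FDA receipt date and, among date ties, the largest PRIMARYID,
then removes any case named on the quarterly deleted-case lists. Rows with
a missing CASEID or an unparseable FDA_DT are quarantined to a rejects
list and counted rather than silently dropped, since silent loss would
break the conservation identities the pipeline asserts (parsed =
kept + duplicates + quarantined; kept = deleted-removed + analyzed).

Drug names are standardized through a synonym table (raw name → generic
name, case-insensitive after whitespace normalization); unmapped names are
kept verbatim and flagged. PTs map to exactly one "primary" SOC through a
bundled mock dictionary shipped as a TSV — real MedDRA is license-gated,
so the dictionary covers only the vocabulary the generator emits, and any
PT outside it is reported in an explicit "unmapped" row.

Age is converted to years from the FAERS unit code (YR ×1, DEC ×10,
MON ÷12, WK ÷52.18, DY ÷365.25, HR ÷8766; other codes → missing). A
report is *serious* iff any outcome code in {DE, LT, HO, DS, CA, RI} is
present — OT-only reports are non-serious, the usual regulatory
convention. Repeated PTs within one report collapse to a single event
occurrence, so one report contributes at most one count to any cell of
any PT's table. Reports whose primary-suspect (PS) drug is the target form
the target population; everything else, including reports that list the
target only as a concomitant and reports with no PS drug at all, is
background.

## Disproportionality statistics

All four statistics operate on the report-level 2×2 table per PT.

**ROR and PRR.** Computed from the standard formulas with a 95% Wald CI on
the log odds ratio. When any cell is zero, the Haldane–Anscombe correction
(+0.5 to every cell) is applied to ROR and PRR only; the Bayesian methods
handle zeros natively. The χ² statistic uses Yates' continuity correction
(configurable off), matching how the MHRA composite criterion
(a ≥ 3, PRR ≥ 2, χ² ≥ 4) is conventionally quoted; thresholds are
inclusive (≥).

**BCPNN information component.** The normative definition here is Monte
Carlo. The margins get Beta(1, 1) priors; the joint cell gets
Beta(g₁, g−g₁) with g₁ = 1 and g chosen so that the prior expectation of
the IC is zero. The three posteriors are sampled independently
(default 100,000 draws, seeded; per-PT seeds are spawned deterministically
from the screen's base seed), and IC draws are log₂ p₁₁/(p₁.p.₁). The
point estimate is the posterior expectation by default (the posterior
median is a config switch); IC025 is the empirical 2.5th percentile. A
deterministic approximation (`bcpnn_ic_approx`) is also provided: the IC
expectation is exact via digamma identities, and the 2.5th percentile
keeps the skewed joint-cell term exact through the incomplete-beta CDF
while integrating the two near-normal marginal terms out by Gauss–Hermite
quadrature. On a validation grid spanning a = 0…55 across margin scales
it agrees with the Monte-Carlo values within 0.02; the worst cases are
a ≤ 1, where a naive normal approximation would be off by ~0.8.

**MGPS / EBGM.** The relative reporting rate λ has the two-component gamma
mixture prior with the published FDA-data fit (α₁=0.2, β₁=0.1, α₂=2.0,
β₂=4.0, w=⅓) that FAERS disproportionality studies conventionally reuse;
the study data do not pin these down at desk scale, and a marginal
maximum-likelihood re-fit over all PT tables is available behind
`fit_mgps_prior` for users with a large table set. Conjugacy gives a
two-gamma posterior with component weights updated through
negative-binomial marginals; EBGM uses the digamma identity for
E[log₂ λ], and EB05 is found by monotone root-finding on the mixture CDF
(verified in tests against 2×10⁶ posterior samples to within 0.01).

**Consensus and ranking.** A PT with fewer than 3 target reports is not
tested. Consensus = AND of the four flags, so on null data the consensus
false-positive count can never exceed the most conservative single
algorithm's — asserted, together with an absolute false-positive bound, on
generated null corpora. Signal listings rank by descending ROR with ties
broken by larger `a`, then PT lexicographically, so exports are
deterministic.

## Time-to-onset model

TTO = event date − therapy start in whole days; therapy start is the
earliest start date among the report's PS-drug therapy rows, and the event
date is the report-level event date (one TTO per report). Reports missing
either date, carrying a partial (YYYY or YYYYMM) date, or showing a
negative interval are excluded and tallied by reason.

The onset distribution is fitted by the two-parameter Weibull MLE using
the profile likelihood: for fixed shape β the scale has the closed form
α = (mean tᵝ)^(1/β), and the remaining one-dimensional score equation in β
is monotone and solved by bracketed root-finding to 1e-12. This makes the
fit exactly scale-equivariant (asserted to 1e-6 in tests) and free of
optimizer tuning; scipy's generic Weibull fit serves as an independent
cross-check in the test suite, not as the implementation. Day-0 onsets
enter the likelihood as 0.5 days (a log(0) guard); the empirical median
and IQR always use the raw values. 95% CIs are Wald intervals on
(log α, log β) from the finite-difference observed information,
back-transformed — the log scale respects positivity; whether the original
analysis used the natural or log scale is not stated, so this choice is
flagged for sensitivity checking. Failure type is read off the shape CI
alone: early if the upper bound is below 1, wear-out if the lower bound
exceeds 1, random otherwise. Fits require n ≥ 10 and reject degenerate
(all-identical) samples.

## Subgroup screens

Stratified screens restrict target and background to the stratum *before*
building tables, so a stratum covering the whole population reproduces the
unstratified screen exactly (asserted in tests). The subgroup screening
rule is the ROR criterion; listings are ranked by target-report frequency.
Age offers both the three-bin scheme (18–44 / 45–64 / ≥65) and the binary
<65 / ≥65 split; reports with unknown sex or age are excluded from the
respective stratifications, not imputed.

The sex-difference test compares female vs male reporting of each PT
within target-drug reports only: ROR > 1 with CI lower bound > 1 is
female-biased, ROR < 1 with CI upper bound < 1 male-biased. P-values use
the Yates χ² unless any expected cell is below 5, in which case Fisher's
exact test is substituted; Benjamini–Hochberg FDR is applied across all
tested PTs, and the export carries log₂ ROR, −log₁₀ p and q per PT for
volcano plotting.

## Descriptive tables

Percentages are 100·count/denominator rounded half-up to two decimals,
which reproduces printed case-proportion tables exactly from their integer
counts. The characteristics table's denominator is the report count;
outcome rows are patient-level and multi-valued, so they may sum above
100%. The SOC distribution's denominator is AE instances (report–PT
pairs), with tiers primary > 5%, secondary 1–5% inclusive, rare < 1% —
boundaries chosen to match the conventional wording; tiering uses the
exact (unrounded) percentage.

## The synthetic corpus

The generator emits the exact ASCII dialect the parser reads, including
the contamination real FAERS brings: duplicate case versions (a fraction
of cases appears twice with a different PRIMARYID and an earlier-or-equal
FDA_DT, 20% of duplicates sharing the date to exercise the PRIMARYID
tie-break), deleted-case lists, orphan table rows left behind by
deduplication, partial and missing dates, negative onset intervals, age
unit codes, raw trade names for the synonym table, and an unmapped PS
drug name in the background. Events are per-(report, PT) independent
Bernoulli draws: target reports carry a planted PT with probability
min(1, rr·baseline) — optionally restricted to one sex — and background
reports with the baseline; reports that sample no event draw one PT from
the null pool, since real reports always list at least one reaction.
Onsets are Weibull(scale, shape) rounded to whole days (zeros allowed —
their handling is the TTO module's job, so the generator does not censor
them).

Defaults mirror the motivating case study's conditions: 563 target
reports, demographic mixes taken as exact count fractions of its printed
characteristics table, onset scale 45.74 days and shape 0.63, 44% of
reports with no computable onset, and a planted association profile
shaped like an antifolate's toxicity spectrum. The background is 20,000
reports — large enough for stable background rates at desk scale while
keeping a full run in seconds; it stands in for the tens of millions of
real FAERS reports, so corpus-level absolute counts (numbers of signals,
SOC percentages) are study-shaped but not reproductions. What the
generator deliberately does not model: correlation between PTs within a
report, drug–drug interactions, reporting-rate drift over calendar time,
and country- or reporter-specific event profiles. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and its recovery of
planted structure, not calibration against real reporting behavior.

Ground truth (planted parameters, injected duplicate and deletion counts,
per-PT carrier counts) is written as a sidecar JSON; tests compare
pipeline output against it but never feed it through the pipeline path.

## Numerical and reproducibility choices

Every stochastic component (generator, BCPNN draws) is seeded; per-PT
BCPNN seeds are spawned from the base seed by index so that adding or
removing thresholds does not reshuffle other PTs' draws. The pipeline
manifest records counts at every stage and is byte-identical for identical
config and seed. Analysis scripts regenerate the corpus deterministically
from one study seed rather than sharing intermediate files, so each can
run standalone.

Problem sizes used in the shipped simulations — 200 replicates of n=316
for Weibull recovery, 200-seed calibration of the generator's null ROR,
corpora of a few hundred to a few thousand reports for recovery and
calibration tests — were chosen so the full suite runs in a few minutes on
one CPU while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* The mock dictionary is a stand-in: one flat PT→SOC map with no MedDRA
  versioning, hierarchy levels, or licensing-faithful vocabulary.
* Only pairwise drug–event disproportionality is implemented; no
  higher-order itemset MGPS, and no interaction modeling beyond
  stratified RORs.
* The Weibull fit handles observed onsets only — no censoring for
  patients still on therapy, matching the source design but limiting
  interpretation.
* Whether a report with no PS drug should be background is a convention;
  it is logged so users can quantify the choice.
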