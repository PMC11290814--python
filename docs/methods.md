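# Methods

## Setting and model

A spontaneous reporting system (SRS) is a passive database of adverse-event
case reports. There is no denominator of drug users, so absolute risks are
unidentifiable; what can be measured is *reporting disproportionality*: for
a (drug, event) pair, whether the fraction of target-drug reports that
mention the event exceeds the corresponding fraction among all other
reports. Every statistic in this package is a function of the case-level
2×2 table

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| all other drugs| c            | d            |

with N = a+b+c+d. A *case* is one deduplicated safety report. A case is
drug-exposed iff it carries a mention of the target concept with a role
code in the configured filter; the default filter is `{PS}` (primary
suspect), the conventional exposure definition for single-drug screens. A
case contributes to the event column once, regardless of how many of its
PTs match (or, at SOC level, how many of its PTs map into the target SOC).

The four measures and intervals are listed in the README. Points worth
making explicit:

- **EBGM as relative reporting ratio.** EBGM is computed as
  aN/((a+b)(a+c)) — the observed/expected reporting ratio — with a Woolf
  log-normal interval. This is *not* the MGPS posterior mean: no
  Gamma-mixture shrinkage is applied. Consequently EBGM here is unstable at
  small a (no shrinkage toward 1), which is why the a ≥ 3 floor and the
  ranked-table view matter.
- **IC/EBGM identity.** IC = log₂(EBGM) exactly, because both are the same
  ratio on different scales. The test suite asserts the identity at 1e-12;
  it also provides a cheap consistency check on any published table that
  prints both columns.
- **V(IC).** The BCPNN literature derives V(IC) from a Bayesian posterior;
  no single closed form is canonical in the frequentist reading used here.
  The default strategy, `"delta-log2"`, transports the Woolf dispersion of
  the other intervals onto the log2 scale: V(IC) = (1/ln 2)²·(1/a + 1/b +
  1/c + 1/d), giving IC ± 2√V(IC). The strategy is a registry
  (`VIC_STRATEGIES`) so a proper Bayesian variance can be added without
  touching callers. Published IC025 values computed under an unstated
  variance are therefore not comparison targets for this package.
- **PRR interval.** The delta-method dispersion on ln PRR,
  √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
- **χ².** The printed 1-df Pearson form without Yates continuity
  correction; verified against `scipy.stats.chi2_contingency(correction=False)`
  to 12 digits on random tables.
- **"N ≥ 3".** The case floor in the ROR and PRR criteria is read as the
  drug–event cell a ≥ 3, the usual reading in disproportionality practice.
- **Zero cells.** Default behaviour is a flagged-undefined estimate
  (`zero_cell=True`) that always classifies negative — silent ±∞ or NaN
  propagation would corrupt ranked tables. A Haldane–Anscombe +0.5
  correction is available (`zero_cell="haldane"`); χ² is always computed
  from the raw integer cells.
- **Monotonicity caveat.** ROR and PRR are strictly increasing in a with
  b, c, d fixed. IC and EBGM are **not**: a new a-case also inflates both
  margins of the expected count, and e.g. (1,1,1,5) → (2,1,1,5) leaves the
  ratio at exactly 2.0. The correct joint property — moving an event case
  from the comparator (c) to the target (a) with margins fixed raises all
  four — is what the property suite asserts.
- **Rounding.** Internal computation is full precision; the formatted
  report writer rounds to 2 decimals.

## Ingest and cleaning

- **Dialect.** The `$`-delimited quarterly ASCII layout with
  DEMO/DRUG/REAC/OUTC tables keyed by `primaryid` (case id ‖ version) and
  `caseid`; delimiter and filename patterns are configurable
  (`FaersDialect`). Malformed rows are counted, never silently dropped;
  a missing mandatory file is a hard error naming the file.
- **Deduplication.** SRS databases resubmit updated versions of the same
  case, including across quarters. One record is kept per `caseid`: latest
  receipt date, ties broken by larger case version, then later file order.
  The rule is deterministic and idempotent, and is applied globally across
  the whole quarter span, not per quarter.
- **Drug normalisation.** Verbatim names are trimmed, internal whitespace
  collapsed, edge punctuation stripped, uppercased, then looked up in a
  synonym → concept dictionary; misses map to the sentinel `UNMAPPED`
  rather than erroring (an unmapped mention is data, not a failure).
- **PT → SOC.** Each PT has exactly one primary SOC. A reaction term
  absent from the hierarchy raises by default (`unknown_pt="error"`),
  because silently dropping reactions corrupts the b/d cells; an opt-in
  `"bucket"` mode routes such terms to an `UNKNOWN` event code instead.
- **Age.** All units are converted to years (MON/12, WK/52.18, DY/365.25,
  HR/8766); a missing unit with an age present is read as years; an
  unrecognised unit yields a missing age.
- **Exclusions.** Cases left with no mappable reaction are excluded and
  counted in the assembly log, so the cleaning funnel (rows read →
  unparseable dates → distinct cases → excluded → assembled) is auditable.
- **Counting units.** SRS summaries mix "events", "cases" and "terms"
  freely; `report_counts` exposes case-level and pair-level counts side by
  side (cases, distinct PTs/SOCs corpus-wide, drug-linked cases, drug-linked
  distinct PTs/SOCs, drug case–PT pairs) so reports can say which is which.

## Descriptive tables

Age bands are ≤19, 20–39, 40–59, 60–79, ≥80 and unknown, with both printed
endpoints inclusive on the floored integer age. Serious-outcome categories
(death, disability, hospitalization, life-threatening) are not mutually
exclusive — a case counts once in each category it carries; remaining FAERS
outcome codes (CA, RI, OT) are reported in an "other" row outside the four
headline categories. All percentages, including the top-k country rows, use
the grand total of cases as denominator and are rounded to 2 decimals.

## Synthetic corpus: what it emulates and what it does not

The generator (`synthetic_data`) emits the same quarterly files the ingest
layer reads, plus a truth directory (final version per case, implanted-pair
ratios, demographic counts, config echo). Study conditions — chosen once,
as defaults, from design considerations:

- **Catalog.** 8 drug concepts with verbatim-spelling noise (synonyms,
  case variants, trailing punctuation) and per-drug role-code mixes; 28 PTs
  across 14 SOCs with baseline per-case probabilities between 0.002 and
  0.25. A case with no sampled drug receives one fallback drug (every FAERS
  case names a drug).
- **Target drug.** Cyclosporine (`RX3008`) appears on 0.4% of reports,
  75% of mentions as primary suspect. The rarity is substantive, not
  cosmetic: the relative reporting ratio aN/((a+b)(a+c)) converges to the
  true rate ratio only when exposed cases are a small fraction of N, so
  recovery experiments are run in the regime where the estimand and the
  implanted parameter coincide.
- **Implantation.** For an implanted (drug, PT, ρ) pair, cases with any
  mention of the drug have the PT probability set to min(1, ρ·baseline);
  nothing else changes. Cases that sample zero reactions are repaired with
  a single fallback PT drawn from the baseline weights *excluding implanted
  PTs*, so both arms of every implanted pair keep exactly their nominal
  probabilities and the true reporting-rate ratio equals ρ by construction.
  (Unimplanted pairs acquire a slight, conservative attenuation from the
  repair; the null-calibration suite covers them.)
- **Duplicates.** A configurable fraction of cases (default 10%) gains a
  second version, value-identical except a receipt date 30–400 days later
  — duplicates exercise the dedup key and nothing else, so closure failures
  localise to joins or to dedup, not both.
- **Demographics.** Gender 65.4% female conditional on known, 12.4%
  missing; ages sampled in the five bands with weights 0.137/0.151/0.295/
  0.344/0.073 conditional on known, 56.3% missing, infants emitted in
  months; 10 countries with a US-dominant mix, 10% missing; outcome-code
  probabilities around 12% hospitalization and 10% death. These echo the
  shape of a large immunosuppressant case series.
- **Determinism.** One `numpy` Generator seeded from the config drives
  every draw; the same seed yields byte-identical files. Emission-only
  draws (verbatim spelling noise) happen after all corpus draws, so the
  in-memory corpus is identical whether or not files are written.

Not emulated: drug co-prescription correlation, temporal reporting trends,
country-specific reporting cultures, partially-updated duplicate versions,
free-text misspellings beyond the catalog variants, and multi-drug
interaction signals. Passing tests therefore demonstrate correctness of
the pipeline's logic and calibration under independence — not robustness to
the confounding structure of real FAERS data.

## Problem sizes and verification

- Unit suites run on hand-built corpora and a 400-case implanted corpus,
  with a quadratic per-case oracle re-deriving every 2×2 table.
- Closure: 1,000 cases, 4 quarters, 10–12% duplicates — generate → read →
  assemble reproduces the truth corpus exactly (case count, per-case
  reaction sets, role codes, demographic fields).
- Null calibration: 5 seeds × {2,000, 20,000} cases, no implanted pairs;
  the PRR false-flag fraction among a ≥ 3 pairs stays ≤ 5% and does not
  grow with corpus size.
- Parameter recovery: ρ ∈ {2, 5, 10}, 100 seeds each at 50,000 cases; the
  EBGM 95% interval covers ρ in ≥ 90 of 100 replicates (observed 97–99).
- Deterministic checks recompute published percentages from their printed
  counts and IC points from printed EBGM values via the log2 identity.

## Known limitations

- No empirical-Bayes shrinkage, no stratified (age/sex/year) tables, no
  multiplicity adjustment across events — the screen is the classical
  unadjusted one, and small-a rows are noisy by design.
- The shipped MedDRA hierarchy and drug dictionary are synthetic teaching
  stand-ins; real analyses must supply licensed MedDRA and a real RxNorm
  mapping through the same CSV interfaces.
- `empirical_rr` and EBGM agree only in the rare-exposure limit; for a
  drug on a large fraction of reports the relative reporting ratio is
  attenuated relative to the rate ratio.
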