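# Methods

## Setting

Spontaneous reporting systems collect unverified post-marketing
adverse-event reports. Disproportionality analysis asks, for a drug–event
pair, whether the pair is reported more often than expected under
independence within the database. The unit of analysis throughout is the
*deduplicated report*: a report contributes once to a cell regardless of
how many times it repeats a preferred term (PT), and once per system organ
class (SOC) at SOC level.

## Statistics

For cells `a` (cohort with event), `b` (cohort without), `c` (comparator
with), `d` (comparator without), `N = a+b+c+d`:

* **ROR** `= ad/bc`, Wald interval on the log scale with
  `SE = √(1/a + 1/b + 1/c + 1/d)`. When any cell is zero the
  Haldane–Anscombe correction adds 0.5 to all four cells and the row is
  flagged `corrected`; the same correction (flagged) backs PRR when
  `c = 0`.
* **PRR** `= [a/(a+b)]/[c/(c+d)]`, paired with the Pearson chi-square
  without continuity correction (a Yates flag exists but is off: the
  published pairing of PRR with plain χ² magnitudes implies no
  correction).
* **BCPNN IC** `= log2[(a+0.5)/(E+0.5)]`, `E = (a+b)(a+c)/N`. The lower
  credibility bound uses the closed-form shrinkage approximation
  `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`. The approximation is the
  2.5% quantile of a Gamma(`a`+½, rate 1+1/(2E)) posterior for the
  co-reporting intensity; `bcpnn_ic_mc` draws that posterior directly and
  is used as the cross-check (closed form vs Monte-Carlo agrees within
  0.15 bits for `a ≥ 3` in the test suite).
* **Signal criteria** (config-overridable; the conventional thresholds are
  used because the source analysis does not print its exact ones):
  ROR — `a ≥ 3` and CI lower bound > 1; PRR — `a ≥ 3`, `PRR ≥ 2`,
  `χ² ≥ 4`; BCPNN — `IC025 > 0`. A pair is a signal when at least one
  criterion holds; the met criteria are listed per row. No
  multiple-testing correction is applied (screening convention); a
  Bonferroni option is deliberately out of scope of the default path.

The default comparator is *all other reports in the store* (full-database
comparator). Because `ROR/PRR = d(a+b)/[b(c+d)]`, ROR > PRR whenever
ROR > 1 — a useful internal consistency check on any output table.

## Deduplication and cohorts

Within each CASEID the version with the latest FDA_DT survives; FDA_DT
ties go to the highest PRIMARYID; a missing FDA_DT sorts earliest. Dedup
runs *before* cohort selection, since report versions can disagree on drug
role. A cohort is the set of deduplicated reports naming the drug in the
primary-suspect (PS) role; a report with two PS-role target drugs counts in
both cohorts, and the pooled column of the profile table sums per-drug
columns (the per-drug counting convention; multi-PS reports are logged).

Outcome codes map DE/LT/HO/DS/CA/RI/OT to death, life-threatening,
hospitalization, disability, congenital anomaly, required intervention and
other serious; a report is serious iff any category applies, and the "SAE
total" row sums the seven category counts (so a report with two outcome
codes contributes twice to the total — this matches how published SAE
totals are tallied against the report-count denominator).

Ages normalise to years via unit codes YR (×1), DEC (×10), MON (÷12),
WK (÷52.14), DY (÷365.25); an unknown code leaves age missing. Bands are
<18, 18–44, 45–64, 65–74, ≥75, unknown. Reporter type folds occupation
codes: MD/PH/OT/RN/HP → healthcare professional, CN → consumer, else
other/unknown (map configurable). Indications take a four-way split
(multiple-sclerosis variants / ulcerative colitis / any other non-missing →
Others / missing → Unknown). Percentages are rounded half-up to two
decimals, with the cohort report count as denominator; median/IQR age uses
known ages only. These demographic conventions are choices of this package
where the source conventions are unstated.

## Subgroups, rankings, death-restricted analysis

A subgroup is a pure predicate over report fields. Subgroup odds ratios
restrict cohort *and* comparator to the stratum before rebuilding tables.
The current quarterly layout has no reliable race field, so "racial"
grouping is approximated by a user-editable reporting-country → region
map. Rankings default to ROR descending (ties: case count descending, then
event label — fully deterministic); `ic` ranking is available. The
death-restricted analysis recomputes the PT-level pipeline inside
death-outcome reports on both sides, and the runner also emits the overall
statistics side by side, because a published death table can be read either
as a re-analysis or as a re-ranking.

## Synthetic-data generator

The generator emulates a FAERS-style extract with a known generative law:

* Exactly one PS drug per case; target cohort sizes are config counts and
  comparator cases draw a drug uniformly from a ≥20-name dummy pool.
* Given the PS drug, each vocabulary PT is an independent Bernoulli with
  probability `p_background × RR(drug, PT)` (RR defaults to 1; a config
  whose product exceeds 1 is rejected naming the pair). Reports with no
  event are resampled until non-empty — so every case has ≥1 REAC row, and
  the per-PT law conditional on a report existing is inflated by
  `1/(1 − P(no event))`, identically in both arms. Tests therefore check
  against this exact conditional law, and the high-frequency filler terms
  keep the inflation small.
* With all RR = 1 the (drug, PT) law factorises — the null model used for
  the independence and false-signal tests.
* A `duplicate_rate` fraction of cases is emitted as 2–3 versions sharing
  the CASEID with strictly increasing PRIMARYID; FDA_DT advances one day
  per version except for a `duplicate_same_date_frac` (default 0.25)
  fraction of versions that keep the prior date, so both the
  latest-date clause and the tie-on-date clause of the dedup rule are
  exercised. The sidecar records the designated surviving version.
* Demographics (sex, age band, country, occupation, outcome codes,
  indication) are categorical draws whose defaults mirror the published
  cohort profile (e.g. 73.7% female, 44.6% unknown age, 66.4% US,
  12.6% hospitalization); a further 10% of DEMO age/sex fields are blanked
  to exercise the Unknown categories. A small share of ages is emitted in
  MON/DEC units to exercise unit conversion. Outcome codes are per-code
  independent Bernoulli draws, so multi-outcome reports occur.
* Determinism: one `numpy` generator seeded from the config; identical
  config + seed gives byte-identical files.

The example configuration scales the three real cohort sizes by 1/20
(fingolimod 4,019 / siponimod 346 / ozanimod 234) over a 30,000-report
comparator — large enough for the planted structure to surface, small
enough that the full analysis chain runs in seconds — and plants relative
risks for the ocular, haematological and cardiac terms that dominate the
published signal tables, including macular oedema and optic neuritis for
all three drugs so the cross-drug shared-signal view is non-trivial.

What the generator does **not** emulate: reporting trends over time (Weber
effect), notoriety bias, drug–drug interactions, correlated PT clusters
within a report, free-text noise beyond simple dose/salt suffixes, and the
legacy pre-2012Q4 ISR-keyed file layout. Passing tests show the chain is
correct under the stated generative law, not that real FAERS data meet that
law.

## Validation experiments (tests and `scripts/acceptance.py`)

* Reference-table values: `a,b,c,d = 10, 90, 100, 9900` gives ROR 11.0,
  PRR 10.0, χ² 74.45, IC 2.724; independence tables give ROR = PRR = 1 and
  χ² = 0; all checked against independent implementations at 1e−9.
* ROR > PRR on every random table with ROR > 1 (10,000 tables).
* Wald-interval coverage: 1,000 multinomial databases at population odds
  ratio 2 and 5 (`n = 10,000`, `a ≥ 5` stratum) — coverage sits in the
  93–97% band.
* Planted-signal recovery: RR = 10 at background 0.01, 500-report cohort
  vs 2,000-report comparator (≈50 expected co-reports), 200 replicate
  studies through generation → dedup → tables → criteria: all three
  criteria fire in ≈100% and the 95% ROR CI contains the planted RR in
  ≈95% of replicates.
* Dedup contract: with 30% duplicated cases the survivor set equals the
  sidecar's designated versions exactly and re-application is a no-op.

Problem sizes above were chosen so each experiment is statistically
informative at desk scale; the published large-database signal values
(top-20 tables, subgroup RORs) depend on the full multi-million-report
extract and are reproduced *structurally* (same table layouts, same
ranking and criteria semantics), not numerically.

## Known limitations

* Disproportionality measures association in a reporting stream, not
  incidence or causality; no confounding adjustment (no regression or
  propensity machinery) is included.
* Only the current PRIMARYID-keyed quarterly dialect is parsed; legacy
  files need a caller-supplied column-rename map after conversion.
* Exact-duplicate detection is by CASEID only; probabilistic record
  linkage across different CASEIDs is out of scope.
* The shipped IME list is illustrative; real screens must supply the
  licensed term list, and PT→SOC mapping requires the licensed MedDRA
  hierarchy.
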