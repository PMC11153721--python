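# pvsignal

Disproportionality signal detection on FAERS-style spontaneous
adverse-event reports, built around the post-marketing safety question:
*which adverse events are reported disproportionately often with the
sphingosine-1-phosphate receptor (S1PR) modulators — fingolimod, siponimod,
ozanimod — used in multiple sclerosis?*

The package is aimed at pharmacovigilance analysts. It implements the whole
chain as a reusable library plus a set of analysis drivers:

1. **Synthetic store generation** — quarterly `$`-delimited DEMO / DRUG /
   REAC / OUTC / INDI / THER files with known statistical structure
   (planted drug–event relative risks, duplicate report versions,
   demographics) and a ground-truth sidecar, so every downstream stage can
   be validated exactly.
2. **Ingest** — parsing the quarterly dialect, joining child tables on
   PRIMARYID, normalising drug names (case folding, dose/salt-token
   stripping) against a generic + brand dictionary.
3. **Deduplication and cohorting** — one report per CASEID (latest FDA_DT,
   ties to the highest PRIMARYID), primary-suspect cohorts per drug, outcome
   seriousness classes, and the clinical-characteristics profile.
4. **Disproportionality statistics** — for each drug–event 2×2 table with
   cells `a, b, c, d` (`N = a+b+c+d`, expected count `E = (a+b)(a+c)/N`):

   * reporting odds ratio `ROR = ad / bc`,
     `95% CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`;
   * proportional reporting ratio `PRR = [a/(a+b)] / [c/(c+d)]` with
     Pearson `χ² = N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)]`;
   * information component `IC = log2[(a + 0.5)/(E + 0.5)]` with the
     shrinkage lower bound
     `IC025 = IC − 3.3(a + 0.5)^−1/2 − 2(a + 0.5)^−3/2`.

   A pair is a signal when at least one criterion holds:
   `a ≥ 3` and ROR CI lower bound > 1; `a ≥ 3`, `PRR ≥ 2` and `χ² ≥ 4`;
   or `IC025 > 0`.
5. **Views** — organ-class (SOC) proportion profiles, age/region subgroup
   RORs, top-N rankings by signal strength, death-restricted re-analysis,
   and the important-medical-event (IME) screen with cross-drug shared
   signals.

## Worked example

```sh
python analysis/01_simulate.py          # synthetic store -> scratch/synthetic_store
python analysis/02_descriptive_profile.py
python analysis/03_signal_tables.py
python analysis/04_subgroups_and_deaths.py
python analysis/05_ime_screen.py
```

Step 1 draws a study-shaped store (three cohorts at 1/20 of the real report
counts plus a 30,000-report comparator, 15% duplicated cases) and prints

```
cases: 34,599  report versions: 40,951  event rows: 52,640
duplicated cases: 5,265
```

Step 2 deduplicates 40,951 report versions down to 34,599 cases and selects
the cohorts (fingolimod 4,019; siponimod 346; ozanimod 234 — the planted
cohort sizes), writing `results/table2.csv`. Step 3 prints each drug's
leading signals, e.g. for fingolimod:

```
lymphocyte count decreased   a= 684 ROR= 52.06 (42.74-63.41) IC= 2.87
macular oedema               a= 585 ROR= 25.49 (21.65-30.02) IC= 2.67
progressive multifocal
  leukoencephalopathy        a= 110 ROR= 20.46 (14.32-29.24) IC= 2.61
```

`a` is the number of cohort reports mentioning the term, the ROR is its
odds ratio against all other reports with the Wald 95% CI, and IC is the
shrinkage information component; every planted relative risk surfaces with
all three criteria met, while unplanted terms stay near ROR = 1. Step 5
intersects IME signals across the three drugs (here optic neuritis is
flagged for all of them, min IC = 1.49).

The same pipeline runs over a real quarterly extract via the CLI:

```sh
pvsignal run --config run.toml
pvsignal signals --store <dir> --drug fingolimod --subset death --out table5.csv
```

with a user-supplied drug dictionary (`name,canonical` CSV), PT→SOC map
(`pt,soc` CSV — the MedDRA hierarchy is licensed and not shipped) and IME
list (`pt` CSV; a small illustrative list is bundled for tests).

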