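#!/usr/bin/env python
"""Step 2 — ingest, deduplicate, cohort, and write the clinical profile.

Reads the quarterly store from step 1, applies the latest-version rule per
CASEID, selects the three primary-suspect cohorts, and writes the
clinical-characteristics table (``results/table2.csv``) and the attrition
log. Prints the headline shares (female %, US %, SAE %) for the pooled
column.
"""

from pathlib import Path

from pvsignal import (AttritionLog, DrugDictionary, deduplicate, describe,
                      read_store, select_cohort)

ROOT = Path(__file__).resolve().parents[1]
STORE = ROOT / "scratch" / "synthetic_store"
RESULTS = ROOT / "results"
DRUGS = ["fingolimod", "siponimod", "ozanimod"]


def load_reports():
    if not STORE.exists():
        raise SystemExit("synthetic store missing - run analysis/01_simulate.py first")
    dictionary = DrugDictionary.from_csv(STORE / "drug_dictionary.csv")
    records, log = read_store(STORE, dictionary=dictionary)
    attrition = AttritionLog()
    n_raw = sum(n for f, n in log.rows_per_file.items() if f.startswith("DEMO"))
    attrition.add("raw report versions", n_raw, n_raw)
    attrition.add("with >=1 adverse-event row", n_raw, len(records))
    reports = deduplicate(records, attrition)
    return reports, attrition


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reports, attrition = load_reports()
    cohorts = {d: select_cohort(reports, d, attrition) for d in DRUGS}
    table = describe(cohorts)
    table.to_csv(RESULTS / "table2.csv", index=False, lineterminator="\n")
    attrition.to_frame().to_csv(RESULTS / "attrition.csv", index=False,
                                lineterminator="\n")
    print(attrition)
    total = sum(len(c) for c in cohorts.values())
    for drug, cohort in cohorts.items():
        print(f"{drug}: {len(cohort):,} reports")
    female = table[(table.variable == "gender") & (table.category == "female")]
    sae = table[(table.variable == "outcome") & (table.category == "SAE total")]
    print(f"pooled reports: {total:,}")
    print(f"pooled female share: {float(female.total_pct.iloc[0]):.2f}%")
    print(f"pooled SAE total: {int(sae.total_n.iloc[0]):,} "
          f"({float(sae.total_pct.iloc[0]):.2f}% of reports)")


if __name__ == "__main__":
    main()
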