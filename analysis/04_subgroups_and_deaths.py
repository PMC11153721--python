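#!/usr/bin/env python
"""Step 4 — subgroup organ-class odds ratios and the death-restricted table.

Restricts cohort and comparator alike to each age subgroup (paediatric <18,
late-onset >50) and to death-outcome reports, rebuilding the 2x2 tables
inside the stratum. Writes ``results/table3_<subgroup>.csv`` and
``results/table5_<drug>.csv``.
"""

import importlib
from pathlib import Path

import pandas as pd

from pvsignal import load_pt_soc_map, top_signals
from pvsignal.stratify import (age_subgroup, death_subset_signals,
                               subgroup_soc_ror)

ROOT = Path(__file__).resolve().parents[1]
STORE = ROOT / "scratch" / "synthetic_store"
RESULTS = ROOT / "results"
DRUGS = ["fingolimod", "siponimod", "ozanimod"]

profile = importlib.import_module("02_descriptive_profile")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reports, _ = profile.load_reports()
    pt_to_soc = load_pt_soc_map(STORE / "pt_soc_map.csv")
    cohorts = {d: [r for r in reports if d in r.canonical_ps_drugs] for d in DRUGS}
    comparators = {d: [r for r in reports if d not in r.canonical_ps_drugs]
                   for d in DRUGS}

    for spec in (age_subgroup("age_lt18", max_years=18),
                 age_subgroup("age_gt50", min_years=50.000001)):
        frames = []
        for drug in DRUGS:
            try:
                sub = subgroup_soc_ror(cohorts[drug], comparators[drug], spec,
                                       pt_to_soc)
            except ValueError:
                print(f"{spec.name}: no {drug} reports in subgroup")
                continue
            sub.insert(0, "drug", drug)
            frames.append(sub)
        if frames:
            table = pd.concat(frames, ignore_index=True)
            table.to_csv(RESULTS / f"table3_{spec.name}.csv", index=False,
                         lineterminator="\n")
            strongest = table.dropna(subset=["ror"]).nlargest(3, "ror")
            print(f"{spec.name}: strongest SOC RORs:")
            for row in strongest.itertuples():
                print(f"  {row.drug} / {row.soc}: N={row.n} ROR={row.ror:.2f}")

    for drug in DRUGS:
        try:
            death = death_subset_signals(cohorts[drug], comparators[drug],
                                         pt_to_soc=pt_to_soc)
        except ValueError:
            print(f"{drug}: no death-outcome reports; table5 skipped")
            continue
        ranked = top_signals(death, n=20)
        ranked.to_csv(RESULTS / f"table5_{drug}.csv", index=False,
                      lineterminator="\n")
        print(f"{drug}: {len(ranked)} death-restricted signals "
              f"(top: {ranked.event.iloc[0] if len(ranked) else '-'})")


if __name__ == "__main__":
    main()
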