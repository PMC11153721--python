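#!/usr/bin/env python
"""Step 3 — disproportionality signals per drug.

For each cohort against the all-other-reports comparator: the PT-level
statistics table, the top-20 ranking by reporting odds ratio
(``results/table4_<drug>.csv``), the forest-plot CSV of flagged signals,
and the organ-class proportion profile. Prints each drug's leading signals
with their planted relative risks in mind.
"""

import importlib
from pathlib import Path

from pvsignal import build_tables, load_pt_soc_map, signal_frame, top_signals
from pvsignal.stratify import soc_proportions

ROOT = Path(__file__).resolve().parents[1]
STORE = ROOT / "scratch" / "synthetic_store"
RESULTS = ROOT / "results"
DRUGS = ["fingolimod", "siponimod", "ozanimod"]

profile = importlib.import_module("02_descriptive_profile")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reports, _ = profile.load_reports()
    pt_to_soc = load_pt_soc_map(STORE / "pt_soc_map.csv")
    for drug in DRUGS:
        cohort = [r for r in reports if drug in r.canonical_ps_drugs]
        comparator = [r for r in reports if drug not in r.canonical_ps_drugs]
        frame = signal_frame(build_tables(cohort, comparator), pt_to_soc=pt_to_soc)
        ranked = top_signals(frame, n=20)
        ranked.to_csv(RESULTS / f"table4_{drug}.csv", index=False,
                      lineterminator="\n")
        frame.loc[frame.signal, ["event", "soc", "a", "ror", "ror_l95", "ror_u95"]
                  ].to_csv(RESULTS / f"forest_{drug}.csv", index=False,
                           lineterminator="\n")
        soc_proportions(cohort, pt_to_soc).to_csv(
            RESULTS / f"soc_profile_{drug}.csv", index=False, lineterminator="\n")
        print(f"\n{drug}: {int(frame.signal.sum())} signalled PTs "
              f"of {len(frame)} observed")
        for row in ranked.head(5).itertuples():
            print(f"  {row.event:<45s} a={int(row.a):4d} "
                  f"ROR={row.ror:7.2f} ({row.ror_l95:.2f}-{row.ror_u95:.2f}) "
                  f"IC={row.ic:5.2f}")


if __name__ == "__main__":
    main()
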