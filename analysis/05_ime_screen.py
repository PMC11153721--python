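#!/usr/bin/env python
"""Step 5 — important-medical-event screen and cross-drug shared signals.

Filters each drug's PT-level signal table to the bundled illustrative IME
term list (``results/ime_<drug>.csv``) and intersects the flagged signals
across drugs, ranking shared terms by their minimum information component
(``results/ime_common.csv``).
"""

import importlib
from pathlib import Path

from pvsignal import (IMEList, build_tables, common_strong_signals,
                      filter_ime, signal_frame)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DRUGS = ["fingolimod", "siponimod", "ozanimod"]

profile = importlib.import_module("02_descriptive_profile")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reports, _ = profile.load_reports()
    ime = IMEList.illustrative()
    tables = {}
    for drug in DRUGS:
        cohort = [r for r in reports if drug in r.canonical_ps_drugs]
        comparator = [r for r in reports if drug not in r.canonical_ps_drugs]
        frame = signal_frame(build_tables(cohort, comparator))
        tables[drug] = filter_ime(frame, ime)
        tables[drug].to_csv(RESULTS / f"ime_{drug}.csv", index=False,
                            lineterminator="\n")
        flagged = tables[drug][tables[drug].signal]
        print(f"{drug}: {len(flagged)} IME signals of {len(tables[drug])} "
              f"IME terms observed")

    common = common_strong_signals(tables)
    common.to_csv(RESULTS / "ime_common.csv", index=False, lineterminator="\n")
    print("\nIMEs signalled for every drug (by min IC):")
    for row in common.itertuples():
        print(f"  {row.event}: min IC = {row.min_ic:.2f}")


if __name__ == "__main__":
    main()
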