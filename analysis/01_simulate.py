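#!/usr/bin/env python
"""Step 1 — generate the synthetic report store.

Draws a study-shaped synthetic spontaneous-report database: three
S1P-receptor-modulator cohorts whose sizes mirror the real extract at 1/20
scale (fingolimod 4,019; siponimod 346; ozanimod 234), a 30,000-report
background comparator, 15% duplicate cases, and planted relative risks for
the ocular / haematological / cardiac terms the published tables flag.
Writes quarterly ``$``-delimited files plus the ground-truth sidecar to
``scratch/synthetic_store``.
"""

from pathlib import Path

from pvsignal import example_config, generate

ROOT = Path(__file__).resolve().parents[1]
STORE = ROOT / "scratch" / "synthetic_store"


def main(seed: int = 20240601) -> None:
    cfg = example_config(scale=1.0, seed=seed)
    study = generate(cfg, STORE)
    n_versions = len(study.tables["DEMO"])
    n_events = len(study.tables["REAC"])
    print(f"store: {STORE}")
    print(f"cases: {len(study.sidecar):,}  report versions: {n_versions:,}  "
          f"event rows: {n_events:,}")
    print(f"duplicated cases: {int(study.sidecar['is_duplicate'].sum()):,}")


if __name__ == "__main__":
    main()
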