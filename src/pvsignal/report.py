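"""End-to-end pipeline: store -> cohorts -> publication-style output bundle.

``run_all`` wires every stage together and writes, under the configured
output directory:

* ``table2.csv`` — clinical-profile table across the configured drugs;
* ``attrition.csv`` / ``attrition.txt`` — the stage-by-stage record counts;
* ``soc_profile_<drug>.csv`` — organ-class proportion profile;
* ``table3_<subgroup>.csv`` — per-SOC subgroup report counts and RORs;
* ``table4_<drug>.csv`` — top-N PT-level signals ranked by signal strength;
* ``table5_<drug>.csv`` — death-restricted top-N signals with the overall
  (unrestricted) statistics side by side, so both readings of a
  death-report table are available;
* ``ime_<drug>.csv`` and ``ime_common.csv`` — important-medical-event screen;
* ``forest_<drug>.csv`` — event, N, ROR and CI bounds, ready for forest
  plotting;
* ``manifest.json`` — config hash, seed, and per-file row counts.

Any stage failure aborts with the stage name; the attrition log reflects the
state reached at failure.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import RunConfig
from .dedup import AttritionLog, Report, deduplicate, describe, select_cohort
from .disproportionality import SignalThresholds, build_tables, signal_frame
from .ime import IMEList, common_strong_signals, filter_ime
from .ingest import DrugDictionary, read_store
from .stratify import (SubgroupSpec, age_subgroup, death_subset_signals,
                       soc_proportions, subgroup_soc_ror, top_signals)

__all__ = ["PipelineError", "RunOutputs", "load_pt_soc_map", "run_all"]

log = logging.getLogger("pvsignal")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, attrition: AttritionLog):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.attrition = attrition


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Preferred-term -> organ-class map from a CSV with columns ``pt,soc``."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["pt"]] = row["soc"]
    if not out:
        raise ValueError(f"{path}: empty PT->SOC map")
    return out


@dataclass
class RunOutputs:
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    attrition: AttritionLog = field(default_factory=AttritionLog)
    row_counts: dict[str, int] = field(default_factory=dict)


def _write(outputs: RunOutputs, name: str, frame: pd.DataFrame) -> None:
    path = outputs.out_dir / name
    frame.to_csv(path, index=False, lineterminator="\n")
    outputs.files[name] = path
    outputs.row_counts[name] = len(frame)


def default_subgroups() -> list[SubgroupSpec]:
    # The two age windows of the published subgroup comparison: paediatric
    # onset (<18) and late onset (>50).
    return [age_subgroup("age_lt18", max_years=18),
            age_subgroup("age_gt50", min_years=50.000001)]


def run_all(config: RunConfig,
            subgroups: list[SubgroupSpec] | None = None) -> RunOutputs:
    """Execute the whole pipeline for ``config``; returns the output bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = RunOutputs(out_dir=out_dir)
    attrition = outputs.attrition
    thresholds = SignalThresholds(min_cases=config.min_cases,
                                  prr_min=config.prr_threshold,
                                  chi2_min=config.chi2_threshold)
    if subgroups is None:
        subgroups = default_subgroups()

    stage = "ingest"
    try:
        dictionary = DrugDictionary.from_csv(config.drug_dictionary)
        records, ingest_log = read_store(config.store_dir,
                                         list(config.quarters) if config.quarters else None,
                                         dictionary)
        n_raw = sum(n for f, n in ingest_log.rows_per_file.items()
                    if f.startswith("DEMO"))
        attrition.add("raw report versions (DEMO rows)", n_raw, n_raw)
        attrition.add("with >=1 adverse-event row", n_raw, len(records))
        log.info("ingest: %d raw versions, %d with events", n_raw, len(records))

        stage = "deduplicate"
        reports = deduplicate(records, attrition)

        stage = "cohorts"
        cohorts: dict[str, list[Report]] = {}
        for drug in config.drugs:
            cohorts[drug] = select_cohort(reports, drug, attrition)
        multi_ps = sum(1 for r in reports
                       if len(r.canonical_ps_drugs & set(config.drugs)) > 1)
        log.info("reports suspected of >1 target drug: %d", multi_ps)
        comparators = {d: [r for r in reports if d not in r.canonical_ps_drugs]
                       for d in config.drugs}

        stage = "describe"
        _write(outputs, "table2.csv", describe(cohorts))

        pt_to_soc: Mapping[str, str] | None = None
        if config.pt_soc_map is not None:
            pt_to_soc = load_pt_soc_map(config.pt_soc_map)

        stage = "signals"
        signals: dict[str, pd.DataFrame] = {}
        for drug in config.drugs:
            tables = build_tables(cohorts[drug], comparators[drug], level="pt")
            sf = signal_frame(tables, pt_to_soc=pt_to_soc, thresholds=thresholds)
            signals[drug] = sf
            _write(outputs, f"table4_{drug}.csv",
                   top_signals(sf, n=config.top_n, min_cases=config.min_cases))
            forest = sf.loc[sf["signal"],
                            ["event", "soc", "a", "ror", "ror_l95", "ror_u95"]]
            _write(outputs, f"forest_{drug}.csv", forest.reset_index(drop=True))

        if pt_to_soc is not None:
            stage = "soc profile"
            for drug in config.drugs:
                _write(outputs, f"soc_profile_{drug}.csv",
                       soc_proportions(cohorts[drug], pt_to_soc))

            stage = "subgroups"
            for spec in subgroups:
                frames = []
                for drug in config.drugs:
                    try:
                        sub = subgroup_soc_ror(cohorts[drug], comparators[drug],
                                               spec, pt_to_soc)
                    except ValueError:
                        continue  # drug has no reports in this subgroup
                    sub.insert(0, "drug", drug)
                    frames.append(sub)
                if frames:
                    _write(outputs, f"table3_{spec.name}.csv",
                           pd.concat(frames, ignore_index=True))

        stage = "death subset"
        for drug in config.drugs:
            try:
                death = death_subset_signals(cohorts[drug], comparators[drug],
                                             pt_to_soc=pt_to_soc,
                                             thresholds=thresholds)
            except ValueError:
                log.info("no death-outcome reports for %s; table5 skipped", drug)
                continue
            ranked = top_signals(death, n=config.top_n, min_cases=config.min_cases)
            overall = signals[drug][["event", "a", "ror", "prr", "chi2", "ic"]]
            merged = ranked.merge(overall, on="event", how="left",
                                  suffixes=("", "_overall"))
            _write(outputs, f"table5_{drug}.csv", merged)

        stage = "ime screen"
        if config.ime_list is not None:
            ime = IMEList.from_csv(config.ime_list)
        else:
            ime = IMEList.illustrative()
        ime_tables: dict[str, pd.DataFrame] = {}
        for drug in config.drugs:
            ime_tables[drug] = filter_ime(signals[drug], ime)
            _write(outputs, f"ime_{drug}.csv", ime_tables[drug])
        if len(ime_tables) >= 2:
            _write(outputs, "ime_common.csv", common_strong_signals(ime_tables))

        stage = "attrition + manifest"
        _write(outputs, "attrition.csv", attrition.to_frame())
        (out_dir / "attrition.txt").write_text(repr(attrition) + "\n")
        outputs.files["attrition.txt"] = out_dir / "attrition.txt"
        manifest = {
            "config_hash": hashlib.sha256(
                repr(sorted(vars(config).items())).encode()).hexdigest(),
            "seed": config.seed,
            "files": {
                name: {"bytes": path.stat().st_size,
                       "rows": outputs.row_counts.get(name)}
                for name, path in sorted(outputs.files.items())
            },
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n")
        outputs.files["manifest.json"] = path
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(stage, exc, attrition) from exc
    return outputs
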