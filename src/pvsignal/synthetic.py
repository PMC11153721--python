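"""Synthetic FAERS-dialect report generator with known statistical structure.

Every emitted case has exactly one primary-suspect (PS) drug. Given that
drug, each preferred term in the configured vocabulary is reported as an
independent Bernoulli draw with probability ``p_background * rr``, where
``rr`` comes from the planted (drug, PT, relative risk) triples and defaults
to 1; cases with no event are resampled until at least one PT is drawn.
Under all-RR-equal-1 the joint law of (drug, PT) therefore factorises into
its marginals, which is what makes the generator a usable null model.

A configurable fraction of cases is emitted as multiple report versions
sharing the CASEID (distinct PRIMARYID, FDA_DT bumped or tied), replicating
the duplicate-version structure the deduplication rule is designed for. A
ground-truth sidecar table (case -> PS drug, PT multiset, designated latest
version) is produced alongside so downstream stages can be checked exactly.

Output files follow the current quarterly ASCII layout: one ``$``-delimited
file per table per quarter (``DEMO13Q2.txt`` ...), first line = header.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SyntheticConfig

__all__ = ["SyntheticStudy", "sample_study", "write_study", "generate"]

TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT", "SEX", "AGE", "AGE_COD",
             "OCCR_COUNTRY", "OCCP_COD"],
    "DRUG": ["PRIMARYID", "CASEID", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "OUTC": ["PRIMARYID", "CASEID", "OUTC_COD"],
    "INDI": ["PRIMARYID", "CASEID", "INDI_PT"],
    "THER": ["PRIMARYID", "CASEID", "START_DT", "END_DT"],
}

_BRAND = {
    "fingolimod": "Gilenya",
    "siponimod": "Mayzent",
    "ozanimod": "Zeposia",
    "ponesimod": "Ponvory",
}

_AGE_RANGES = {"<18": (5, 17), "18-44": (18, 44), "45-64": (45, 64),
               "65-74": (65, 74), ">=75": (75, 94)}

_OUTCOME_CODES = ["DE", "LT", "HO", "DS", "CA", "RI", "OT"]


@dataclass
class SyntheticStudy:
    """In-memory bundle: the six FAERS-style tables plus the truth sidecar."""

    config: SyntheticConfig
    tables: dict[str, pd.DataFrame]
    sidecar: pd.DataFrame


def _quarter_start(label: str) -> date:
    year, q = int(label[:4]), int(label[5])
    return date(year, 3 * (q - 1) + 1, 1)


def _quarter_ndays(label: str) -> int:
    year, q = int(label[:4]), int(label[5])
    if q == 4:
        nxt = date(year + 1, 1, 1)
    else:
        nxt = date(year, 3 * q + 1, 1)
    return (nxt - _quarter_start(label)).days


def _yyyymmdd(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _sample_events(n: int, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n x K Bernoulli matrix with empty rows resampled until non-empty."""
    if p.sum() <= 0:
        raise ValueError("event probabilities sum to zero; cannot force >=1 PT")
    mat = rng.random((n, p.size)) < p
    empty = ~mat.any(axis=1)
    while empty.any():
        mat[empty] = rng.random((int(empty.sum()), p.size)) < p
        empty = ~mat.any(axis=1)
    return mat


def _drugname_variant(drug: str, k: int) -> str:
    """Deterministic raw-string variants exercising name normalisation."""
    brand = _BRAND.get(drug)
    variants = [drug.upper(), f"{drug.capitalize()} HCL"]
    if brand is not None:
        variants += [brand.upper(), f"{brand} 0.5 MG"]
    return variants[k % len(variants)]


def sample_study(config: SyntheticConfig) -> SyntheticStudy:
    """Draw one synthetic store from the configured generative law."""
    config.validate()
    demo_dist = config.demographics.normalised()
    rng = np.random.default_rng(config.seed)

    drugs: list[str] = []
    for drug, n in config.n_reports_per_drug.items():
        drugs += [drug] * n
    pool = list(config.background_drug_pool)
    bg_idx = rng.integers(0, len(pool), size=config.n_background_reports)
    drugs += [pool[i] for i in bg_idx]
    n_cases = len(drugs)
    caseids = np.arange(1_000_000, 1_000_000 + n_cases)

    quarters = list(config.quarter_range)
    q_idx = rng.integers(0, len(quarters), size=n_cases)
    day_frac = rng.random(n_cases)
    fda_dates = []
    for i in range(n_cases):
        q = quarters[q_idx[i]]
        fda_dates.append(_quarter_start(q) + timedelta(days=int(day_frac[i] * _quarter_ndays(q))))

    def draw(dist: dict[str, float], size: int) -> np.ndarray:
        cats = list(dist)
        return rng.choice(len(cats), size=size, p=[dist[c] for c in cats]), cats

    sex_i, sex_cats = draw(demo_dist.sex, n_cases)
    band_i, band_cats = draw(demo_dist.age_band, n_cases)
    ages = np.full(n_cases, np.nan)
    band_u = rng.random(n_cases)
    for j, band in enumerate(band_cats):
        if band == "unknown":
            continue
        lo, hi = _AGE_RANGES[band]
        sel = band_i == j
        ages[sel] = lo + np.floor(band_u[sel] * (hi - lo + 1))
    country_i, country_cats = draw(demo_dist.country, n_cases)
    occp_i, occp_cats = draw(demo_dist.occp_cod, n_cases)
    out_mat = rng.random((n_cases, len(_OUTCOME_CODES))) < np.array(
        [demo_dist.outcome_probs.get(c, 0.0) for c in _OUTCOME_CODES]
    )
    indi_i, indi_cats = draw(demo_dist.indication, n_cases)

    # Events: one Bernoulli matrix per PS drug so planted RRs apply per group.
    vocab = list(config.pt_vocabulary)
    pts = [e.pt for e in vocab]
    p_bg = np.array([e.p_background for e in vocab])
    rr = config.rr_lookup()
    drug_arr = np.array(drugs)
    events = np.zeros((n_cases, len(vocab)), dtype=bool)
    group_order = list(config.n_reports_per_drug) + ["__background__"]
    for drug in group_order:
        sel = (
            ~np.isin(drug_arr, list(config.n_reports_per_drug))
            if drug == "__background__"
            else drug_arr == drug
        )
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        p_eff = p_bg if drug == "__background__" else np.array(
            [min(1.0, e.p_background * rr.get((drug, e.pt), 1.0)) for e in vocab]
        )
        events[sel] = _sample_events(n_sel, p_eff, rng)

    blank_age = rng.random(n_cases) < config.missing_demo_frac
    blank_sex = rng.random(n_cases) < config.missing_demo_frac
    age_cod_u = rng.random(n_cases)  # small fraction emitted in non-year units
    conc = rng.random(n_cases) < config.concomitant_rate
    conc_drug = rng.integers(0, len(pool), size=n_cases)
    name_variant = rng.integers(0, 4, size=n_cases)
    ther_offset = rng.integers(10, 400, size=n_cases)
    ther_end_blank = rng.random(n_cases) < 0.5

    dup = rng.random(n_cases) < config.duplicate_rate
    n_extra = np.where(rng.random(n_cases) < 0.2, 2, 1) * dup
    same_date = rng.random((n_cases, 2)) < config.duplicate_same_date_frac

    demo_rows, drug_rows, reac_rows, outc_rows, indi_rows, ther_rows = \
        [], [], [], [], [], []
    sidecar_rows = []
    for i in range(n_cases):
        caseid = int(caseids[i])
        case_pts = [pts[k] for k in np.flatnonzero(events[i])]
        versions = 1 + int(n_extra[i])
        offset = 0
        last_pid = None
        for v in range(versions):
            if v > 0 and not same_date[i, v - 1]:
                offset += 1
            pid = caseid * 10 + v
            last_pid = pid
            fda = _yyyymmdd(fda_dates[i] + timedelta(days=offset))
            if blank_age[i] or np.isnan(ages[i]):
                age_s, age_cod = "", ""
            elif age_cod_u[i] < 0.03:
                age_s, age_cod = str(int(ages[i] * 12)), "MON"
            elif age_cod_u[i] < 0.05:
                age_s, age_cod = f"{ages[i] / 10:.1f}", "DEC"
            else:
                age_s, age_cod = str(int(ages[i])), "YR"
            demo_rows.append((pid, caseid, fda,
                              "" if blank_sex[i] else sex_cats[sex_i[i]],
                              age_s, age_cod,
                              country_cats[country_i[i]], occp_cats[occp_i[i]]))
            d = drugs[i]
            if d in config.n_reports_per_drug:
                raw, ai = _drugname_variant(d, int(name_variant[i])), d.upper()
            else:
                raw, ai = d, d
            drug_rows.append((pid, caseid, "PS", raw, ai))
            if conc[i]:
                cd = pool[conc_drug[i]]
                drug_rows.append((pid, caseid, "C", cd, cd))
            for pt in case_pts:
                reac_rows.append((pid, caseid, pt))
            for k, code in enumerate(_OUTCOME_CODES):
                if out_mat[i, k]:
                    outc_rows.append((pid, caseid, code))
            if indi_cats[indi_i[i]]:
                indi_rows.append((pid, caseid, indi_cats[indi_i[i]]))
            start = _yyyymmdd(fda_dates[i] - timedelta(days=int(ther_offset[i])))
            end = "" if ther_end_blank[i] else _yyyymmdd(fda_dates[i])
            ther_rows.append((pid, caseid, start, end))
        sidecar_rows.append({
            "caseid": caseid,
            "true_drug": drugs[i],
            "true_pts": ";".join(case_pts),
            "n_versions": versions,
            "latest_primaryid": last_pid,
            "is_duplicate": versions > 1,
            "quarter": quarters[q_idx[i]],
        })

    tables = {
        "DEMO": pd.DataFrame(demo_rows, columns=TABLE_COLUMNS["DEMO"]),
        "DRUG": pd.DataFrame(drug_rows, columns=TABLE_COLUMNS["DRUG"]),
        "REAC": pd.DataFrame(reac_rows, columns=TABLE_COLUMNS["REAC"]),
        "OUTC": pd.DataFrame(outc_rows, columns=TABLE_COLUMNS["OUTC"]),
        "INDI": pd.DataFrame(indi_rows, columns=TABLE_COLUMNS["INDI"]),
        "THER": pd.DataFrame(ther_rows, columns=TABLE_COLUMNS["THER"]),
    }
    return SyntheticStudy(config=config, tables=tables,
                          sidecar=pd.DataFrame(sidecar_rows))


def write_study(study: SyntheticStudy, out_dir: str | Path) -> list[Path]:
    """Write the quarterly ``$``-delimited bundle plus sidecar and reference CSVs.

    Deterministic: identical study content yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # Duplicate versions can slip past a quarter boundary by a day; file the
    # whole case under its base-report quarter so versions stay together.
    case_quarter = dict(zip(study.sidecar["caseid"], study.sidecar["quarter"]))
    for name, frame in study.tables.items():
        df = frame.copy()
        df["_quarter"] = df["CASEID"].map(case_quarter)
        for quarter, sub in sorted(df.groupby("_quarter")):
            yy = quarter[2:4]
            path = out / f"{name}{yy}Q{quarter[5]}.txt"
            # stable sort keeps within-report row order (e.g. PS drug first)
            sub = sub.drop(columns="_quarter").sort_values("PRIMARYID", kind="mergesort")
            lines = ["$".join(TABLE_COLUMNS[name])]
            for row in sub.itertuples(index=False):
                lines.append("$".join(str(v) for v in row))
            path.write_text("\n".join(lines) + "\n", newline="\n")
            written.append(path)

    sidecar_path = out / "sidecar_truth.csv"
    study.sidecar.sort_values("caseid").to_csv(sidecar_path, index=False,
                                               lineterminator="\n")
    written.append(sidecar_path)

    pt_soc = pd.DataFrame(
        [(e.pt, e.soc) for e in study.config.pt_vocabulary], columns=["pt", "soc"]
    )
    pt_soc.to_csv(out / "pt_soc_map.csv", index=False, lineterminator="\n")
    written.append(out / "pt_soc_map.csv")

    dict_rows = []
    for drug in study.config.n_reports_per_drug:
        dict_rows.append((drug, drug))
        if drug in _BRAND:
            dict_rows.append((_BRAND[drug].lower(), drug))
    pd.DataFrame(dict_rows, columns=["name", "canonical"]).to_csv(
        out / "drug_dictionary.csv", index=False, lineterminator="\n"
    )
    written.append(out / "drug_dictionary.csv")
    return written


def generate(config: SyntheticConfig, out_dir: str | Path) -> SyntheticStudy:
    """Sample a study from ``config`` and write its quarterly bundle to ``out_dir``."""
    study = sample_study(config)
    write_study(study, out_dir)
    return study


def study_records(study: SyntheticStudy, dictionary=None) -> list:
    """Assemble RawRecords straight from the in-memory tables (no file IO).

    Semantically identical to writing the bundle and reading it back with
    :func:`pvsignal.ingest.read_store`; used where many replicate studies
    must flow through the pipeline.
    """
    from collections import defaultdict

    from .ingest import (DrugMention, RawRecord, map_drug, normalize_sex,
                         parse_age, classify_reporter)

    children: dict[str, dict[int, list]] = {}
    for table in ("DRUG", "REAC", "OUTC", "INDI"):
        by_pid = defaultdict(list)
        for row in study.tables[table].itertuples(index=False):
            by_pid[int(row.PRIMARYID)].append(row)
        children[table] = by_pid

    records = []
    for row in study.tables["DEMO"].itertuples(index=False):
        pid = int(row.PRIMARYID)
        rec = RawRecord(
            primaryid=pid,
            caseid=str(row.CASEID),
            fda_dt=str(row.FDA_DT),
            sex=normalize_sex(str(row.SEX)),
            age_years=parse_age(str(row.AGE), str(row.AGE_COD)),
            country=str(row.OCCR_COUNTRY),
            reporter=classify_reporter(str(row.OCCP_COD)),
        )
        for d in children["DRUG"].get(pid, []):
            mention = DrugMention(name_raw=d.DRUGNAME, prod_ai_raw=d.PROD_AI,
                                  role=d.ROLE_COD)
            if dictionary is not None:
                mention.canonical = map_drug(mention, dictionary)
            rec.drugs.append(mention)
        rec.events = [r.PT for r in children["REAC"].get(pid, [])]
        rec.outcomes = {o.OUTC_COD for o in children["OUTC"].get(pid, [])}
        rec.indications = [i.INDI_PT for i in children["INDI"].get(pid, [])]
        if rec.events:
            records.append(rec)
    return records
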