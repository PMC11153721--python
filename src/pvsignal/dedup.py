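"""Report deduplication, cohort selection and the descriptive profile.

Spontaneous reporting systems receive successive versions of the same case;
per the standard quarterly-extract convention a case is reduced to a single
report by keeping, within each CASEID, the version with the latest FDA_DT,
breaking FDA_DT ties by the highest PRIMARYID. Deduplication is applied
before any cohort selection.

A cohort for a drug is the set of deduplicated reports carrying that drug in
the primary-suspect (PS) role. ``describe`` produces the clinical-profile
table (gender, age bands, median/IQR age, country, reporting year, reporter
type, outcome categories, indication groups) with percentages over the
cohort report count, rounded half-up to two decimals. The pure aggregation
path (`aggregate_profile`) is exposed separately so externally tallied
counts can be pushed through the identical arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import RawRecord

__all__ = [
    "Report",
    "AttritionLog",
    "OUTCOME_CATEGORIES",
    "deduplicate",
    "select_cohort",
    "classify_outcomes",
    "age_band",
    "round_half_up",
    "percent",
    "tally_profile",
    "aggregate_profile",
    "describe",
]

#: FAERS outcome code -> seriousness category.
OUTCOME_CATEGORIES: dict[str, str] = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}

AGE_BANDS = ("<18", "18-44", "45-64", "65-74", ">=75", "unknown")

#: Default four-way indication grouping (exact match after case-folding).
DEFAULT_INDICATION_MAP: dict[str, str] = {
    "multiple sclerosis": "Multiple sclerosis",
    "relapsing-remitting multiple sclerosis": "Multiple sclerosis",
    "relapsing multiple sclerosis": "Multiple sclerosis",
    "secondary progressive multiple sclerosis": "Multiple sclerosis",
    "ulcerative colitis": "Ulcerative colitis",
}


@dataclass
class Report:
    """One deduplicated safety report (a single surviving case version)."""

    caseid: str
    primaryid: int
    fda_dt: str
    sex: str
    age_years: float | None
    age_band: str
    country: str
    reporter: str
    year: str
    events: list[str]
    outcomes: set[str]
    serious_categories: set[str]
    canonical_ps_drugs: set[str]
    indication_group: str

    @property
    def is_serious(self) -> bool:
        return bool(self.serious_categories)


class AttritionLog:
    """Ordered (stage, records in, records out) entries; counts never increase."""

    def __init__(self) -> None:
        self.stages: list[tuple[str, int, int]] = []

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"attrition stage {stage!r}: out {n_out} > in {n_in}")
        self.stages.append((stage, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "records_in", "records_out"])

    def __repr__(self) -> str:
        body = "\n".join(f"  {s}: {i} -> {o}" for s, i, o in self.stages)
        return f"AttritionLog(\n{body}\n)"


def classify_outcomes(outcome_codes: Iterable[str]) -> set[str]:
    """Map OUTC codes to seriousness categories; unrecognised codes are ignored."""
    return {OUTCOME_CATEGORIES[c] for c in outcome_codes if c in OUTCOME_CATEGORIES}


def age_band(age_years: float | None) -> str:
    if age_years is None or not np.isfinite(age_years):
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    if age_years < 75:
        return "65-74"
    return ">=75"


def group_indication(indications: Sequence[str],
                     indication_map: Mapping[str, str] = DEFAULT_INDICATION_MAP) -> str:
    """Four-way split: known group / Others (any other non-missing) / Unknown."""
    named = [i for i in indications if i.strip()]
    if not named:
        return "Unknown"
    for ind in named:
        group = indication_map.get(ind.strip().casefold())
        if group is not None:
            return group
    return "Others"


def _to_report(rec: RawRecord,
               indication_map: Mapping[str, str] = DEFAULT_INDICATION_MAP) -> Report:
    return Report(
        caseid=rec.caseid,
        primaryid=rec.primaryid,
        fda_dt=rec.fda_dt,
        sex=rec.sex,
        age_years=rec.age_years,
        age_band=age_band(rec.age_years),
        country=rec.country,
        reporter=rec.reporter,
        year=rec.fda_dt[:4] if rec.fda_dt else "unknown",
        events=list(rec.events),
        outcomes=set(rec.outcomes),
        serious_categories=classify_outcomes(rec.outcomes),
        canonical_ps_drugs={m.canonical for m in rec.drugs
                            if m.role == "PS" and m.canonical},
        indication_group=group_indication(rec.indications, indication_map),
    )


def deduplicate(records: Sequence[RawRecord],
                attrition: AttritionLog | None = None,
                indication_map: Mapping[str, str] = DEFAULT_INDICATION_MAP,
                ) -> list[Report]:
    """One report per CASEID: keep max FDA_DT, ties broken by max PRIMARYID.

    A missing FDA_DT sorts earliest. Output is sorted by CASEID, so the
    operation is deterministic and idempotent.
    """
    best: dict[str, RawRecord] = {}
    for rec in records:
        key = (rec.fda_dt or "00000000", rec.primaryid)
        incumbent = best.get(rec.caseid)
        if incumbent is None or key > (incumbent.fda_dt or "00000000", incumbent.primaryid):
            best[rec.caseid] = rec
    reports = [_to_report(best[cid], indication_map) for cid in sorted(best)]
    if attrition is not None:
        attrition.add("deduplicate (one report per CASEID)", len(records), len(reports))
    return reports


def select_cohort(reports: Sequence[Report], drug: str,
                  attrition: AttritionLog | None = None) -> list[Report]:
    """Reports in which ``drug`` appears in the primary-suspect role."""
    known = sorted({d for r in reports for d in r.canonical_ps_drugs})
    if drug not in known:
        raise ValueError(f"unknown drug label {drug!r}; known labels: {known}")
    cohort = [r for r in reports if drug in r.canonical_ps_drugs]
    if attrition is not None:
        attrition.add(f"select PS cohort: {drug}", len(reports), len(cohort))
    return cohort


def round_half_up(x: float | Decimal, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denom: int, ndigits: int = 2) -> float:
    """Percentage with half-up rounding; 0 when the denominator is 0."""
    if denom == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(denom)).quantize(q, ROUND_HALF_UP))


# --- descriptive profile -------------------------------------------------

_PROFILE_VARIABLES = ("gender", "age_band", "country", "year", "reporter",
                      "outcome", "indication")


def tally_profile(cohort: Sequence[Report]) -> dict[str, dict[str, int]]:
    """Category counts per profile variable for one cohort."""
    tally: dict[str, dict[str, int]] = {v: {} for v in _PROFILE_VARIABLES}

    def bump(var: str, cat: str) -> None:
        tally[var][cat] = tally[var].get(cat, 0) + 1

    for r in cohort:
        bump("gender", r.sex)
        bump("age_band", r.age_band)
        bump("country", "United States" if r.country.strip().upper() == "US"
             else "Other/Unknown")
        bump("year", r.year)
        bump("reporter", r.reporter)
        for cat in sorted(r.serious_categories):
            bump("outcome", cat)
        bump("indication", r.indication_group)
    return tally


def aggregate_profile(counts_per_drug: Mapping[str, dict[str, dict[str, int]]],
                      denominators: Mapping[str, int]) -> pd.DataFrame:
    """Turn per-drug category counts into the profile table with totals.

    ``counts_per_drug`` maps drug -> variable -> category -> count;
    ``denominators`` maps drug -> cohort report count. The pooled column sums
    counts and denominators across drugs (a report suspected of two target
    drugs therefore contributes to both per-drug columns and twice to the
    pooled one, matching the per-drug counting convention). The SAE total row
    sums the seven outcome-category counts. All percentages use the report
    count as denominator and half-up rounding to two decimals.
    """
    drugs = list(counts_per_drug)
    total_denom = sum(denominators[d] for d in drugs)
    rows = []

    variables: dict[str, list[str]] = {}
    for d in drugs:
        for var, cats in counts_per_drug[d].items():
            variables.setdefault(var, [])
            for cat in cats:
                if cat not in variables[var]:
                    variables[var].append(cat)
    for var in variables:
        if var == "age_band":
            variables[var] = [b for b in AGE_BANDS if b in variables[var]]
        elif var == "outcome":
            order = list(OUTCOME_CATEGORIES.values())
            variables[var] = [c for c in order if c in variables[var]]
        else:
            variables[var] = sorted(variables[var])

    for var, cats in variables.items():
        for cat in cats:
            row: dict[str, object] = {"variable": var, "category": cat}
            total = 0
            for d in drugs:
                n = counts_per_drug[d].get(var, {}).get(cat, 0)
                row[f"{d}_n"] = n
                row[f"{d}_pct"] = percent(n, denominators[d])
                total += n
            row["total_n"] = total
            row["total_pct"] = percent(total, total_denom)
            rows.append(row)
        if var == "outcome":
            row = {"variable": "outcome", "category": "SAE total"}
            total = 0
            for d in drugs:
                n = sum(counts_per_drug[d].get("outcome", {}).values())
                row[f"{d}_n"] = n
                row[f"{d}_pct"] = percent(n, denominators[d])
                total += n
            row["total_n"] = total
            row["total_pct"] = percent(total, total_denom)
            rows.append(row)

    head = {"variable": "reports", "category": "Number of reports"}
    for d in drugs:
        head[f"{d}_n"] = denominators[d]
        head[f"{d}_pct"] = 100.0 if denominators[d] else 0.0
    head["total_n"] = total_denom
    head["total_pct"] = 100.0 if total_denom else 0.0
    return pd.DataFrame([head] + rows)


def describe(cohorts: Mapping[str, Sequence[Report]]) -> pd.DataFrame:
    """Clinical-profile table for one or more cohorts plus the pooled column.

    Includes a ``median (IQR)`` age row computed over reports with known age.
    """
    counts = {d: tally_profile(c) for d, c in cohorts.items()}
    denoms = {d: len(c) for d, c in cohorts.items()}
    table = aggregate_profile(counts, denoms)

    age_row: dict[str, object] = {"variable": "age_years", "category": "median (IQR)"}
    for d, cohort in cohorts.items():
        ages = sorted(r.age_years for r in cohort if r.age_years is not None)
        if ages:
            q1, q3 = np.percentile(ages, [25, 75])
            age_row[f"{d}_n"] = len(ages)
            age_row[f"{d}_pct"] = float("nan")
            age_row[f"{d}_median_iqr"] = (
                f"{round_half_up(median(ages)):.2f} "
                f"({round_half_up(float(q1)):.2f}-{round_half_up(float(q3)):.2f})"
            )
        else:
            age_row[f"{d}_n"] = 0
            age_row[f"{d}_pct"] = float("nan")
            age_row[f"{d}_median_iqr"] = ""
    return pd.concat([table, pd.DataFrame([age_row])], ignore_index=True)
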