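"""Aggregate views over a cohort: organ-class profile, subgroup odds ratios,
top-N signal ranking and the death-restricted analysis.

Subgroups are pure predicates over reports (age bands, geographic "racial"
region derived from the reporting country, fatal outcome); both the cohort
and the comparator are restricted by the same predicate before the 2x2
tables are rebuilt, so a subgroup odds ratio is conditioned on membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .dedup import Report, percent
from .disproportionality import (SignalThresholds, build_tables, ror_stats,
                                 signal_frame)

__all__ = [
    "SubgroupSpec",
    "age_subgroup",
    "region_subgroup",
    "DEFAULT_REGION_MAP",
    "soc_proportions",
    "subgroup_soc_ror",
    "top_signals",
    "death_subset_signals",
]


@dataclass(frozen=True)
class SubgroupSpec:
    """Named pure predicate over Report fields."""

    name: str
    predicate: Callable[[Report], bool]

    def filter(self, reports: Sequence[Report]) -> list[Report]:
        return [r for r in reports if self.predicate(r)]


def age_subgroup(name: str, min_years: float | None = None,
                 max_years: float | None = None) -> SubgroupSpec:
    """Age-window subgroup on known ages, e.g. ``age_subgroup("<18", max_years=18)``
    (max exclusive, min inclusive)."""

    def pred(r: Report) -> bool:
        if r.age_years is None:
            return False
        if min_years is not None and r.age_years < min_years:
            return False
        return max_years is None or r.age_years < max_years

    return SubgroupSpec(name=name, predicate=pred)


#: Reporting-country -> broad geographic group, standing in for the race
#: field the current file layout lacks. User-editable.
DEFAULT_REGION_MAP: dict[str, str] = {
    "US": "White (European-American)", "CA": "White (European-American)",
    "GB": "White (European-American)", "DE": "White (European-American)",
    "FR": "White (European-American)", "IT": "White (European-American)",
    "ES": "White (European-American)", "AU": "White (European-American)",
    "JP": "Asian", "CN": "Asian", "KR": "Asian", "IN": "Asian", "TW": "Asian",
    "NG": "Black (African-American)", "ZA": "Black (African-American)",
}


def region_subgroup(group: str,
                    region_map: Mapping[str, str] = DEFAULT_REGION_MAP) -> SubgroupSpec:
    def pred(r: Report) -> bool:
        return region_map.get(r.country.strip().upper(),
                              "Other/Unknown") == group
    return SubgroupSpec(name=f"region:{group}", predicate=pred)


def death_subgroup() -> SubgroupSpec:
    return SubgroupSpec(name="death reports",
                        predicate=lambda r: "death" in r.serious_categories)


def soc_proportions(cohort: Sequence[Report],
                    pt_to_soc: Mapping[str, str]) -> pd.DataFrame:
    """Event-level organ-class profile: share of all reported events per SOC.

    Every PT occurrence (distinct per report) counts as one event; PTs absent
    from the map fall into the ``unmapped`` bucket. Percentages half-up to
    two decimals, so the column sums to 100 up to rounding slack.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    lookup = {k.casefold(): v for k, v in pt_to_soc.items()}
    counts: dict[str, int] = {}
    for r in cohort:
        for pt in set(e.casefold() for e in r.events):
            soc = lookup.get(pt, "unmapped")
            counts[soc] = counts.get(soc, 0) + 1
    total = sum(counts.values())
    rows = [{"soc": soc, "n_events": n, "pct": percent(n, total)}
            for soc, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows)


def subgroup_soc_ror(cohort: Sequence[Report], comparator: Sequence[Report],
                     spec: SubgroupSpec, pt_to_soc: Mapping[str, str],
                     ) -> pd.DataFrame:
    """Per-SOC report count and ROR within one subgroup (both arms restricted).

    Organ classes with no cohort report in the subgroup are listed with the
    ROR left absent, mirroring the dash convention of printed tables.
    """
    sub_cohort = spec.filter(cohort)
    sub_comp = spec.filter(comparator)
    if not sub_cohort:
        raise ValueError(f"subgroup {spec.name!r} holds no cohort reports")
    tables = build_tables(sub_cohort, sub_comp, level="soc", pt_to_soc=pt_to_soc)
    rows = []
    for soc in sorted(set(pt_to_soc.values()) | set(tables)):
        t = tables.get(soc)
        if t is None:
            rows.append({"soc": soc, "n": 0, "ror": float("nan"),
                         "ror_l95": float("nan"), "ror_u95": float("nan"),
                         "corrected": False})
        else:
            ror, (lo, hi), corrected = ror_stats(t)
            rows.append({"soc": soc, "n": int(t.a), "ror": ror, "ror_l95": lo,
                         "ror_u95": hi, "corrected": corrected})
    return pd.DataFrame(rows)


def top_signals(signals: pd.DataFrame, n: int = 20, rank_key: str = "ror",
                min_cases: int = 3) -> pd.DataFrame:
    """Rows meeting any signal criterion with a >= ``min_cases``, ranked.

    Descending by ``rank_key`` (``ror`` or ``ic``), ties broken by case count
    descending then event label ascending, so the order is fully determined.
    """
    if rank_key not in ("ror", "ic"):
        raise ValueError("rank_key must be 'ror' or 'ic'")
    hits = signals[signals["signal"] & (signals["a"] >= min_cases)].copy()
    hits = hits.sort_values([rank_key, "a", "event"],
                            ascending=[False, False, True], kind="mergesort")
    return hits.head(n).reset_index(drop=True)


def death_subset_signals(cohort: Sequence[Report], comparator: Sequence[Report],
                         pt_to_soc: Mapping[str, str] | None = None,
                         thresholds: SignalThresholds = SignalThresholds(),
                         ) -> pd.DataFrame:
    """PT-level signal table recomputed within death-outcome reports only."""
    spec = death_subgroup()
    sub_cohort = spec.filter(cohort)
    sub_comp = spec.filter(comparator)
    if not sub_cohort:
        raise ValueError("cohort has no death-outcome reports")
    tables = build_tables(sub_cohort, sub_comp, level="pt")
    return signal_frame(tables, pt_to_soc=pt_to_soc, thresholds=thresholds)
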