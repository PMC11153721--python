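"""Disproportionality statistics on drug-event 2x2 tables.

For a drug-event pair, reports are cross-classified as

    =============  ==========  =============
                   with event  without event
    target drug        a            b
    comparator         c            d
    =============  ==========  =============

and three measures are computed:

* reporting odds ratio ``ROR = (a d)/(b c)`` with the 95% Wald interval on
  the log scale, ``exp(ln ROR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``;
* proportional reporting ratio ``PRR = [a/(a+b)] / [c/(c+d)]`` paired with
  the Pearson chi-square ``N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``
  (no continuity correction by default);
* Bayesian confidence propagation information component
  ``IC = log2((a + 0.5)/(E + 0.5))`` with expected count
  ``E = (a+b)(a+c)/N``, and the closed-form shrinkage lower bound
  ``IC025 = IC - 3.3 (a + 0.5)^(-1/2) - 2 (a + 0.5)^(-3/2)``. A Monte-Carlo
  quantile of the gamma posterior behind the shrinkage point estimate is
  available for cross-checking (``bcpnn_ic_mc``).

A pair is flagged as a signal when at least one criterion holds (the
conventional thresholds, overridable via ``SignalThresholds``):
ROR: a >= 3 and CI lower bound > 1; PRR: a >= 3, PRR >= 2 and chi2 >= 4;
BCPNN: IC025 > 0. Zero cells take the Haldane-Anscombe +0.5 correction on
all four cells, flagged in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .dedup import Report

__all__ = [
    "ContingencyTable",
    "SignalThresholds",
    "SignalStats",
    "ror_stats",
    "prr_stats",
    "bcpnn_ic",
    "bcpnn_ic_mc",
    "apply_criteria",
    "build_tables",
    "compute_stats",
    "signal_frame",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug-event pair against a comparator set."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under independence, E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> "ContingencyTable":
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalThresholds:
    min_cases: int = 3
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0


@dataclass
class SignalStats:
    """All three disproportionality measures plus the signal decision."""

    event: str
    soc: str | None
    table: ContingencyTable
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    corrected: bool = False
    criteria_met: set[str] = field(default_factory=set)

    @property
    def n_cases(self) -> float:
        return self.table.a

    @property
    def signal(self) -> bool:
        return bool(self.criteria_met)


def ror_stats(t: ContingencyTable) -> tuple[float, tuple[float, float], bool]:
    """ROR and its Wald 95% CI; zero cells take +0.5 on all cells (flagged)."""
    corrected = t.has_zero_cell()
    u = t.corrected() if corrected else t
    ror = (u.a * u.d) / (u.b * u.c)
    se = math.sqrt(1 / u.a + 1 / u.b + 1 / u.c + 1 / u.d)
    lo, hi = math.exp(math.log(ror) - _Z95 * se), math.exp(math.log(ror) + _Z95 * se)
    return ror, (lo, hi), corrected


def _chi2_pearson(t: ContingencyTable, yates: bool = False) -> float:
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(0.0, diff - t.n / 2)
    return t.n * diff * diff / denom


def prr_stats(t: ContingencyTable, yates: bool = False) -> tuple[float, float, bool]:
    """PRR and Pearson chi-square; c = 0 takes +0.5 on all cells (flagged)."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR undefined: an entire table row is empty")
    corrected = t.c == 0
    u = t.corrected() if corrected else t
    prr = (u.a / (u.a + u.b)) / (u.c / (u.c + u.d))
    return prr, _chi2_pearson(u, yates=yates), corrected


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Shrinkage information component and its closed-form 2.5% bound."""
    a = t.a
    ic = math.log2((a + 0.5) / (t.expected + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


def bcpnn_ic_mc(t: ContingencyTable, n_samples: int = 50_000,
                rng: np.random.Generator | None = None,
                q: float = 0.025) -> float:
    """Monte-Carlo posterior quantile of the information component.

    The observed count is modelled as Poisson with mean mu around the
    independence expectation E; under the standard shrinkage prior
    (gamma with shape 1/2 and rate 1/(2E)) the posterior of mu is
    Gamma(a + 1/2, rate 1 + 1/(2E)) and IC = log2(mu / E). The closed-form
    bound in :func:`bcpnn_ic` approximates the q = 0.025 quantile of this
    posterior; this sampler is the independent check.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    e = t.expected
    if e <= 0:
        return float("nan")
    rate = 1.0 + 0.5 / e
    mu = rng.gamma(shape=t.a + 0.5, scale=1.0 / rate, size=n_samples)
    return float(np.quantile(np.log2(mu / e), q))


def apply_criteria(stats: SignalStats,
                   thresholds: SignalThresholds = SignalThresholds()) -> SignalStats:
    """Attach the met-criteria set; a signal needs at least one of the three."""
    met: set[str] = set()
    if stats.n_cases >= thresholds.min_cases and stats.ror_ci95[0] > thresholds.ror_ci_lower:
        met.add("ROR")
    if (stats.n_cases >= thresholds.min_cases and stats.prr >= thresholds.prr_min
            and stats.chi2 >= thresholds.chi2_min):
        met.add("PRR")
    if stats.ic025 > thresholds.ic025_min:
        met.add("BCPNN")
    return replace(stats, criteria_met=met)


def _report_event_sets(reports: Sequence[Report], level: str,
                       pt_to_soc: Mapping[str, str] | None) -> list[set[str]]:
    if level == "pt":
        return [{e.casefold() for e in r.events} for r in reports]
    if pt_to_soc is None:
        raise ValueError("PT->SOC map required at SOC level")
    lookup = {k.casefold(): v for k, v in pt_to_soc.items()}
    return [{lookup.get(e.casefold(), "unmapped") for e in r.events} for r in reports]


def build_tables(cohort: Sequence[Report], comparator: Sequence[Report],
                 level: Literal["pt", "soc"] = "pt",
                 pt_to_soc: Mapping[str, str] | None = None,
                 ) -> dict[str, ContingencyTable]:
    """2x2 tables for every event observed in the cohort.

    A report contributes once per distinct PT (or once per SOC at SOC level,
    however many of its PTs fall under it). Events never seen in the cohort
    (a = 0) are not emitted.
    """
    if not comparator:
        raise ValueError("comparator set is empty")
    cohort_sets = _report_event_sets(cohort, level, pt_to_soc)
    comp_sets = _report_event_sets(comparator, level, pt_to_soc)
    a_counts: dict[str, int] = {}
    for s in cohort_sets:
        for ev in s:
            a_counts[ev] = a_counts.get(ev, 0) + 1
    c_counts: dict[str, int] = {ev: 0 for ev in a_counts}
    for s in comp_sets:
        for ev in s:
            if ev in c_counts:
                c_counts[ev] += 1
    n_cohort, n_comp = len(cohort), len(comparator)
    return {
        ev: ContingencyTable(a, n_cohort - a, c_counts[ev], n_comp - c_counts[ev])
        for ev, a in sorted(a_counts.items())
    }


def compute_stats(event: str, t: ContingencyTable,
                  soc: str | None = None,
                  thresholds: SignalThresholds = SignalThresholds(),
                  yates: bool = False) -> SignalStats:
    """All three measures plus the criteria decision for one table."""
    ror, ci, ror_corr = ror_stats(t)
    prr, chi2, prr_corr = prr_stats(t, yates=yates)
    ic, ic025 = bcpnn_ic(t)
    stats = SignalStats(event=event, soc=soc, table=t, ror=ror, ror_ci95=ci,
                        prr=prr, chi2=chi2, ic=ic, ic025=ic025,
                        corrected=ror_corr or prr_corr)
    return apply_criteria(stats, thresholds)


def signal_frame(tables: Mapping[str, ContingencyTable],
                 pt_to_soc: Mapping[str, str] | None = None,
                 thresholds: SignalThresholds = SignalThresholds(),
                 yates: bool = False) -> pd.DataFrame:
    """Per-event statistics table (one row per event, sorted by event label)."""
    soc_lookup = {k.casefold(): v for k, v in (pt_to_soc or {}).items()}
    rows = []
    for event, t in tables.items():
        s = compute_stats(event, t, soc=soc_lookup.get(event), thresholds=thresholds,
                          yates=yates)
        rows.append({
            "event": s.event,
            "soc": s.soc if s.soc is not None else "",
            "a": s.table.a,
            "ror": s.ror,
            "ror_l95": s.ror_ci95[0],
            "ror_u95": s.ror_ci95[1],
            "prr": s.prr,
            "chi2": s.chi2,
            "ic": s.ic,
            "ic025": s.ic025,
            "criteria_met": "|".join(sorted(s.criteria_met)),
            "corrected": s.corrected,
            "signal": s.signal,
        })
    return pd.DataFrame(rows, columns=["event", "soc", "a", "ror", "ror_l95",
                                       "ror_u95", "prr", "chi2", "ic", "ic025",
                                       "criteria_met", "corrected", "signal"])
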