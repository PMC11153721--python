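"""Important-medical-event (IME) screening of signal tables.

An IME list is a curated set of preferred terms considered serious or
clinically important regardless of the reported outcome. The screen is a
pure filter: statistics pass through unchanged. The package ships a small
illustrative term list for tests and examples
(``pvsignal/data/ime_illustrative.csv``); production use should supply the
licensed list as a one-column ``pt`` CSV.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["IMEList", "filter_ime", "common_strong_signals"]


@dataclass(frozen=True)
class IMEList:
    """Case-folded PT label set with a version tag."""

    terms: frozenset[str]
    version: str = "unversioned"

    @classmethod
    def from_terms(cls, terms, version: str = "unversioned") -> "IMEList":
        return cls(frozenset(t.strip().casefold() for t in terms if t.strip()),
                   version)

    @classmethod
    def from_csv(cls, path: str | Path, version: str | None = None) -> "IMEList":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if rows and "pt" not in rows[0]:
            raise ValueError(f"{path}: expected a 'pt' column")
        return cls.from_terms((r["pt"] for r in rows),
                              version or Path(path).stem)

    @classmethod
    def illustrative(cls) -> "IMEList":
        """The small demonstration list bundled with the package."""
        path = resources.files("pvsignal") / "data" / "ime_illustrative.csv"
        with resources.as_file(path) as p:
            return cls.from_csv(p, version="illustrative")

    def __contains__(self, pt: str) -> bool:
        return pt.strip().casefold() in self.terms


def filter_ime(signals: pd.DataFrame, ime: IMEList) -> pd.DataFrame:
    """Rows whose event is on the IME list; statistics are untouched."""
    mask = signals["event"].str.strip().str.casefold().isin(ime.terms)
    out = signals[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn("no signal-table event appears on the IME list",
                      stacklevel=2)
    return out


def common_strong_signals(per_drug: Mapping[str, pd.DataFrame],
                          k: int | None = None) -> pd.DataFrame:
    """PTs flagged as signals in *every* drug's table, with per-drug N and IC.

    Ordered by the minimum information component across drugs, descending
    (ties by event label), so the leading rows are the terms most strongly
    shared. Needs at least two drug tables.
    """
    if len(per_drug) < 2:
        raise ValueError("common_strong_signals needs tables for >= 2 drugs")
    signalled: list[set[str]] = []
    for df in per_drug.values():
        signalled.append(set(df.loc[df["signal"], "event"].str.casefold()))
    shared = set.intersection(*signalled)
    rows = []
    for event in shared:
        row: dict[str, object] = {"event": event}
        ics = []
        for drug, df in per_drug.items():
            hit = df[df["event"].str.casefold() == event].iloc[0]
            row[f"{drug}_n"] = hit["a"]
            row[f"{drug}_ic"] = hit["ic"]
            ics.append(float(hit["ic"]))
        row["min_ic"] = min(ics)
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(["min_ic", "event"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out.head(k) if k is not None else out
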