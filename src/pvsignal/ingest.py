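"""Readers for FAERS-dialect quarterly tables and drug-name normalisation.

Supports the current (2012Q4 onward) PRIMARYID-keyed layout only; a
``rename_map`` argument lets callers adapt files whose headers differ (e.g.
converted legacy extracts). Files are ``$``-delimited with no quoting, one
record per line, first line = header. Lines whose field count does not match
the header are skipped and counted; a quarter is rejected if more than 1% of
a file's lines are malformed.

One ``RawRecord`` is assembled per DEMO row, with DRUG/REAC/OUTC/INDI child
rows attached through PRIMARYID. Records with no adverse-event (REAC) rows
are dropped and counted — a report with no event carries no analysable
information for a 2x2 design.
"""

from __future__ import annotations

import csv
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DrugMention",
    "RawRecord",
    "DrugDictionary",
    "IngestLog",
    "normalize_name",
    "map_drug",
    "read_quarter",
    "read_store",
    "find_quarters",
]

REQUIRED_TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER")

EXPECTED_COLUMNS: dict[str, set[str]] = {
    "DEMO": {"PRIMARYID", "CASEID", "FDA_DT", "SEX", "AGE", "AGE_COD",
             "OCCR_COUNTRY", "OCCP_COD"},
    "DRUG": {"PRIMARYID", "CASEID", "ROLE_COD", "DRUGNAME", "PROD_AI"},
    "REAC": {"PRIMARYID", "CASEID", "PT"},
    "OUTC": {"PRIMARYID", "CASEID", "OUTC_COD"},
    "INDI": {"PRIMARYID", "CASEID", "INDI_PT"},
    "THER": {"PRIMARYID", "CASEID", "START_DT", "END_DT"},
}

#: Trailing tokens stripped during name normalisation: salt forms and
#: dose/formulation noise commonly appended to DRUGNAME strings.
DEFAULT_STOP_TOKENS = frozenset({
    "hcl", "hydrochloride", "sodium", "tartrate", "besylate", "fumarate",
    "mg", "mcg", "ml", "tablet", "tablets", "capsule", "capsules", "oral",
    "injection", "solution",
})

_DOSE_RE = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|%)?$")

# Age unit codes -> factor converting the stored value to years.
AGE_UNIT_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.14,
                     "DY": 1 / 365.25}

_HCP_CODES = frozenset({"MD", "PH", "OT", "RN", "HP"})
_CONSUMER_CODES = frozenset({"CN", "CSM"})


def normalize_name(raw: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> str:
    """Case-fold, collapse whitespace, and strip trailing dose/salt tokens."""
    tokens = raw.casefold().split()
    while tokens and (tokens[-1] in stop_tokens or _DOSE_RE.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


class DrugDictionary:
    """Map of normalised generic/brand name strings to canonical drug labels."""

    def __init__(self, entries: dict[str, str]):
        self.entries: dict[str, str] = {}
        for name, canonical in entries.items():
            key = normalize_name(name)
            if not key:
                continue
            if self.entries.get(key, canonical) != canonical:
                raise ValueError(
                    f"alias {key!r} maps to both {self.entries[key]!r} and {canonical!r}"
                )
            self.entries[key] = canonical

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        """Load alias rows from a CSV with columns ``name,canonical``."""
        entries: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["name"]] = row["canonical"]
        return cls(entries)

    @classmethod
    def s1pr_default(cls) -> "DrugDictionary":
        """Generic + brand aliases for the approved S1P-receptor modulators."""
        return cls({
            "fingolimod": "fingolimod", "gilenya": "fingolimod",
            "siponimod": "siponimod", "mayzent": "siponimod",
            "ozanimod": "ozanimod", "zeposia": "ozanimod",
            "ponesimod": "ponesimod", "ponvory": "ponesimod",
        })

    def lookup(self, raw: str) -> str | None:
        return self.entries.get(normalize_name(raw))

    @property
    def canonical_labels(self) -> set[str]:
        return set(self.entries.values())


@dataclass
class DrugMention:
    name_raw: str
    prod_ai_raw: str
    role: str  # PS / SS / C / I
    canonical: str | None = None


@dataclass
class RawRecord:
    """One pre-deduplication report version (one DEMO row plus children)."""

    primaryid: int
    caseid: str
    fda_dt: str  # YYYYMMDD or "" when missing
    sex: str  # male / female / unknown
    age_years: float | None
    country: str
    reporter: str  # consumer / healthcare professional / other/unknown
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)
    indications: list[str] = field(default_factory=list)


@dataclass
class IngestLog:
    """Structured row counts per quarter: file sizes, orphans, drops."""

    rows_per_file: dict[str, int] = field(default_factory=dict)
    malformed_per_file: dict[str, int] = field(default_factory=dict)
    orphan_rows: dict[str, int] = field(default_factory=dict)
    dropped_no_events: int = 0

    def merge(self, other: "IngestLog") -> None:
        for attr in ("rows_per_file", "malformed_per_file", "orphan_rows"):
            mine, theirs = getattr(self, attr), getattr(other, attr)
            for k, v in theirs.items():
                mine[k] = mine.get(k, 0) + v
        self.dropped_no_events += other.dropped_no_events


def map_drug(mention: DrugMention, dictionary: DrugDictionary) -> str | None:
    """Resolve a mention to its canonical label: DRUGNAME first, then PROD_AI."""
    return dictionary.lookup(mention.name_raw) or dictionary.lookup(mention.prod_ai_raw)


def _read_table(path: Path, table: str,
                rename_map: dict[str, str] | None) -> tuple[list[dict[str, str]], int]:
    """Parse one ``$``-delimited file into row dicts; returns (rows, n_malformed)."""
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: file is empty")
    header = [h.strip() for h in lines[0].split("$")]
    if rename_map:
        header = [rename_map.get(h, h) for h in header]
    missing = EXPECTED_COLUMNS[table] - set(header)
    if missing:
        raise ValueError(f"{path}: unrecognised header; missing columns {sorted(missing)}")
    ncol = len(header)
    rows: list[dict[str, str]] = []
    bad = 0
    for line in lines[1:]:
        if not line:
            continue
        fields = line.split("$")
        if len(fields) != ncol:
            bad += 1
            continue
        rows.append(dict(zip(header, fields)))
    n_data = len(rows) + bad
    if n_data and bad / n_data > 0.01:
        raise ValueError(f"{path}: {bad}/{n_data} lines malformed (> 1%)")
    return rows, bad


def parse_age(age: str, age_cod: str) -> float | None:
    """AGE + unit code -> age in years; unknown unit or unparsable -> None."""
    age = age.strip()
    if not age:
        return None
    factor = AGE_UNIT_TO_YEARS.get(age_cod.strip().upper() or "YR")
    if factor is None:
        return None
    try:
        return float(age) * factor
    except ValueError:
        return None


def classify_reporter(occp_cod: str,
                      hcp_codes: frozenset[str] = _HCP_CODES,
                      consumer_codes: frozenset[str] = _CONSUMER_CODES) -> str:
    code = occp_cod.strip().upper()
    if code in hcp_codes:
        return "healthcare professional"
    if code in consumer_codes:
        return "consumer"
    return "other/unknown"


def normalize_sex(sex: str) -> str:
    return {"F": "female", "M": "male"}.get(sex.strip().upper(), "unknown")


def quarter_filename(table: str, quarter: str) -> str:
    return f"{table}{quarter[2:4]}Q{quarter[5]}.txt"


def read_quarter(dir_path: str | Path, quarter: str,
                 dictionary: DrugDictionary | None = None,
                 rename_map: dict[str, str] | None = None,
                 ) -> tuple[list[RawRecord], IngestLog]:
    """Read one quarter's six files and assemble RawRecords keyed by PRIMARYID."""
    dir_path = Path(dir_path)
    log = IngestLog()
    raw: dict[str, list[dict[str, str]]] = {}
    for table in REQUIRED_TABLES:
        path = dir_path / quarter_filename(table, quarter)
        if not path.exists():
            raise FileNotFoundError(f"required file missing for {quarter}: {path}")
        rows, bad = _read_table(path, table, rename_map)
        raw[table] = rows
        log.rows_per_file[path.name] = len(rows)
        log.malformed_per_file[path.name] = bad

    records: dict[int, RawRecord] = {}
    for row in raw["DEMO"]:
        pid = int(row["PRIMARYID"])
        if pid in records:
            raise ValueError(f"duplicate PRIMARYID {pid} within quarter {quarter}")
        records[pid] = RawRecord(
            primaryid=pid,
            caseid=row["CASEID"].strip(),
            fda_dt=row["FDA_DT"].strip(),
            sex=normalize_sex(row["SEX"]),
            age_years=parse_age(row["AGE"], row["AGE_COD"]),
            country=row["OCCR_COUNTRY"].strip(),
            reporter=classify_reporter(row["OCCP_COD"]),
        )

    children: dict[str, dict[int, list[dict[str, str]]]] = {}
    for table in ("DRUG", "REAC", "OUTC", "INDI"):
        by_pid: dict[int, list[dict[str, str]]] = defaultdict(list)
        orphans = 0
        for row in raw[table]:
            pid = int(row["PRIMARYID"])
            if pid in records:
                by_pid[pid].append(row)
            else:
                orphans += 1
        children[table] = by_pid
        log.orphan_rows[f"{table}{quarter[2:4]}Q{quarter[5]}"] = orphans

    out: list[RawRecord] = []
    for pid in sorted(records):
        rec = records[pid]
        for row in children["DRUG"].get(pid, []):
            mention = DrugMention(
                name_raw=row["DRUGNAME"].strip(),
                prod_ai_raw=row["PROD_AI"].strip(),
                role=row["ROLE_COD"].strip().upper(),
            )
            if dictionary is not None:
                mention.canonical = map_drug(mention, dictionary)
            rec.drugs.append(mention)
        rec.events = [r["PT"].strip() for r in children["REAC"].get(pid, [])]
        rec.outcomes = {r["OUTC_COD"].strip().upper()
                        for r in children["OUTC"].get(pid, []) if r["OUTC_COD"].strip()}
        rec.indications = [r["INDI_PT"].strip() for r in children["INDI"].get(pid, [])]
        if not rec.events:
            log.dropped_no_events += 1
            continue
        out.append(rec)
    return out, log


def find_quarters(dir_path: str | Path) -> list[str]:
    """Quarters for which a DEMO file exists in ``dir_path``, sorted."""
    quarters = []
    for path in Path(dir_path).glob("DEMO*Q*.txt"):
        m = re.match(r"DEMO(\d\d)Q(\d)\.txt$", path.name)
        if m:
            yy = int(m.group(1))
            year = 2000 + yy if yy < 70 else 1900 + yy
            quarters.append(f"{year}Q{m.group(2)}")
    return sorted(quarters)


def read_store(dir_path: str | Path, quarters: list[str] | None = None,
               dictionary: DrugDictionary | None = None,
               rename_map: dict[str, str] | None = None,
               ) -> tuple[list[RawRecord], IngestLog]:
    """Read every (or the given) quarter under ``dir_path`` into one record list."""
    if quarters is None:
        quarters = find_quarters(dir_path)
    if not quarters:
        raise FileNotFoundError(f"no quarterly DEMO files found under {dir_path}")
    all_records: list[RawRecord] = []
    log = IngestLog()
    for quarter in quarters:
        recs, qlog = read_quarter(dir_path, quarter, dictionary, rename_map)
        all_records.extend(recs)
        log.merge(qlog)
    return all_records, log
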