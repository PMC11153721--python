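"""Configuration objects for the synthetic generator and the full pipeline run.

``SyntheticConfig`` fixes the generative law of a synthetic spontaneous-report
store: cohort sizes per suspect drug, a PT vocabulary with background
reporting probabilities, planted (drug, PT, relative-risk) triples,
duplicate-version injection, and the categorical demographic distributions
that populate the DEMO table. ``RunConfig`` points the end-to-end pipeline at
a store and its reference tables.

Both can be loaded from a TOML file (see ``docs/methods.md`` for the schema).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "PtEntry",
    "PlantedSignal",
    "Demographics",
    "SyntheticConfig",
    "RunConfig",
    "quarter_labels",
    "example_config",
]


def quarter_labels(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels, e.g. ``quarter_labels("2010Q4", "2011Q2")``."""
    sy, sq = int(start[:4]), int(start[5])
    ey, eq = int(end[:4]), int(end[5])
    if (sy, sq) > (ey, eq):
        raise ValueError(f"quarter range is empty: {start}..{end}")
    out = []
    y, q = sy, sq
    while (y, q) <= (ey, eq):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


@dataclass(frozen=True)
class PtEntry:
    """One preferred term: its organ class and background reporting probability."""

    pt: str
    soc: str
    p_background: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_background < 1.0:
            raise ValueError(
                f"background probability for {self.pt!r} must be in (0,1), "
                f"got {self.p_background}"
            )


@dataclass(frozen=True)
class PlantedSignal:
    """A (drug, PT) pair whose reporting probability is multiplied by ``rr``."""

    drug: str
    pt: str
    rr: float

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise ValueError(f"relative risk must be >= 0, got {self.rr}")


def _norm(dist: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValueError("distribution has no mass")
    return {k: v / total for k, v in dist.items()}


@dataclass(frozen=True)
class Demographics:
    """Categorical distributions used to fill DEMO/OUTC/INDI fields.

    ``outcome_probs`` are per-code marginal probabilities (a report may carry
    several outcome codes, or none); everything else is a categorical
    distribution normalised at construction. The empty-string category means
    "field left blank".
    """

    sex: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.7371, "M": 0.2123, "": 0.0506}
    )
    age_band: Mapping[str, float] = field(
        default_factory=lambda: {
            "<18": 0.0070,
            "18-44": 0.2613,
            "45-64": 0.2557,
            "65-74": 0.0269,
            ">=75": 0.0027,
            "unknown": 0.4464,
        }
    )
    country: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.6635, "DE": 0.12, "GB": 0.08, "JP": 0.06, "": 0.0765}
    )
    occp_cod: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.6152, "MD": 0.20, "PH": 0.10, "OT": 0.0718, "": 0.0130}
    )
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "DE": 0.0137,
            "LT": 0.0135,
            "HO": 0.1259,
            "DS": 0.0138,
            "CA": 0.0015,
            "RI": 0.0003,
            "OT": 0.3749,
        }
    )
    indication: Mapping[str, float] = field(
        default_factory=lambda: {
            "Multiple sclerosis": 0.7847,
            "Ulcerative colitis": 0.0100,
            "Hypertension": 0.0078,
            "": 0.1975,
        }
    )

    def normalised(self) -> "Demographics":
        return Demographics(
            sex=_norm(self.sex),
            age_band=_norm(self.age_band),
            country=_norm(self.country),
            occp_cod=_norm(self.occp_cod),
            outcome_probs=dict(self.outcome_probs),
            indication=_norm(self.indication),
        )


_DEFAULT_POOL = tuple(f"COMPARATOR{i:02d}" for i in range(1, 25))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic report store.

    Events are sampled per PT as independent Bernoulli draws given the
    report's primary-suspect drug, with probability
    ``p_background * rr(drug, pt)`` (rr defaults to 1); reports with no event
    are resampled until non-empty, so every emitted case has at least one
    REAC row. A ``duplicate_rate`` fraction of cases is emitted as two or
    three versions sharing the CASEID, with strictly increasing PRIMARYID and
    FDA_DT bumped by one day per version except for a
    ``duplicate_same_date_frac`` fraction of versions that keep the original
    FDA_DT (so both clauses of the latest-version rule are exercised).
    """

    n_reports_per_drug: Mapping[str, int]
    n_background_reports: int
    pt_vocabulary: Sequence[PtEntry]
    planted_signals: Sequence[PlantedSignal] = ()
    duplicate_rate: float = 0.0
    duplicate_same_date_frac: float = 0.25
    background_drug_pool: Sequence[str] = _DEFAULT_POOL
    demographics: Demographics = field(default_factory=Demographics)
    quarter_range: Sequence[str] = field(
        default_factory=lambda: quarter_labels("2010Q4", "2023Q2")
    )
    missing_demo_frac: float = 0.10
    concomitant_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if not self.n_reports_per_drug:
            raise ValueError("n_reports_per_drug must name at least one drug")
        for drug, n in self.n_reports_per_drug.items():
            if n <= 0:
                raise ValueError(f"n_reports_per_drug[{drug!r}] must be positive, got {n}")
        if self.n_background_reports <= 0:
            raise ValueError("n_background_reports must be positive")
        if not self.pt_vocabulary:
            raise ValueError("pt_vocabulary is empty")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not 0.0 <= self.duplicate_same_date_frac <= 1.0:
            raise ValueError("duplicate_same_date_frac must be in [0, 1]")
        if len(self.background_drug_pool) < 20:
            raise ValueError("background_drug_pool must hold at least 20 names")
        if not self.quarter_range:
            raise ValueError("quarter_range is empty")
        pts = {e.pt for e in self.pt_vocabulary}
        if len(pts) != len(self.pt_vocabulary):
            raise ValueError("pt_vocabulary has duplicate PT labels")
        drugs = set(self.n_reports_per_drug)
        p_by_pt = {e.pt: e.p_background for e in self.pt_vocabulary}
        for s in self.planted_signals:
            if s.drug not in drugs:
                raise ValueError(f"planted signal names unknown drug {s.drug!r}")
            if s.pt not in pts:
                raise ValueError(f"planted signal names unknown PT {s.pt!r}")
            if p_by_pt[s.pt] * s.rr > 1.0:
                raise ValueError(
                    f"planted pair ({s.drug!r}, {s.pt!r}): background probability "
                    f"{p_by_pt[s.pt]} x RR {s.rr} exceeds 1"
                )

    def rr_lookup(self) -> dict[tuple[str, str], float]:
        return {(s.drug, s.pt): s.rr for s in self.planted_signals}

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class RunConfig:
    """Inputs for one end-to-end pipeline run over a quarterly-file store."""

    store_dir: Path
    drugs: Sequence[str]
    drug_dictionary: Path
    pt_soc_map: Path | None = None
    ime_list: Path | None = None
    out_dir: Path = Path("results")
    quarters: Sequence[str] | None = None  # None = every quarter found in store_dir
    min_cases: int = 3
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    top_n: int = 20
    seed: int = 0

    def validate(self) -> None:
        for label, p in (
            ("store_dir", self.store_dir),
            ("drug_dictionary", self.drug_dictionary),
            ("pt_soc_map", self.pt_soc_map),
            ("ime_list", self.ime_list),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} does not exist: {p}")
        if not self.drugs:
            raise ValueError("drugs list is empty")
        if self.min_cases < 1 or self.prr_threshold <= 0 or self.chi2_threshold < 0:
            raise ValueError("thresholds must be positive")


def _config_from_dict(d: dict) -> SyntheticConfig:
    vocab = [PtEntry(*row) if not isinstance(row, dict) else PtEntry(**row)
             for row in d.pop("pt_vocabulary")]
    planted = [
        PlantedSignal(*row) if not isinstance(row, dict) else PlantedSignal(**row)
        for row in d.pop("planted_signals", [])
    ]
    demo = d.pop("demographics", None)
    qr = d.pop("quarter_range", None)
    kwargs = dict(d, pt_vocabulary=vocab, planted_signals=planted)
    if demo is not None:
        kwargs["demographics"] = Demographics(**demo)
    if qr is not None:
        kwargs["quarter_range"] = (
            quarter_labels(qr["start"], qr["end"]) if isinstance(qr, dict) else list(qr)
        )
    return SyntheticConfig(**kwargs)


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    """Read a ``SyntheticConfig`` from a TOML file (``[synthetic]`` table or root)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = _config_from_dict(dict(raw.get("synthetic", raw)))
    cfg.validate()
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    """Read a ``RunConfig`` from a TOML file (``[run]`` table or root)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    d = dict(raw.get("run", raw))
    for key in ("store_dir", "drug_dictionary", "pt_soc_map", "ime_list", "out_dir"):
        if key in d and d[key] is not None:
            d[key] = Path(d[key])
    return RunConfig(**d)


# A compact study-shaped default: three S1P-receptor-modulator cohorts whose
# relative sizes mirror the real report counts (80,384 : 6,913 : 4,681 at
# 1/20 scale), a background comparator, and planted relative risks for the
# ocular/haematological terms that dominate the published signal tables.
_EXAMPLE_VOCAB: tuple[tuple[str, str, float], ...] = (
    ("Macular oedema", "Eye disorders", 0.002),
    ("Optic neuritis", "Nervous system disorders", 0.003),
    ("Blindness", "Eye disorders", 0.002),
    ("Vision blurred", "Eye disorders", 0.008),
    ("Leukopenia", "Blood and lymphatic system disorders", 0.003),
    ("Lymphopenia", "Blood and lymphatic system disorders", 0.002),
    ("Lymphocyte count decreased", "Investigations", 0.002),
    ("Heart rate decreased", "Investigations", 0.004),
    ("Bradycardia", "Cardiac disorders", 0.005),
    ("Atrioventricular block first degree", "Cardiac disorders", 0.001),
    ("Hemiparesis", "Nervous system disorders", 0.003),
    ("Headache", "Nervous system disorders", 0.06),
    ("Dizziness", "Nervous system disorders", 0.04),
    ("Seizure", "Nervous system disorders", 0.006),
    ("Progressive multifocal leukoencephalopathy", "Infections and infestations", 0.0005),
    ("Pneumonia", "Infections and infestations", 0.012),
    ("Urinary tract infection", "Infections and infestations", 0.010),
    ("Nasopharyngitis", "Infections and infestations", 0.015),
    ("Basal cell carcinoma", "Neoplasms benign, malignant and unspecified", 0.002),
    ("Breast cancer", "Neoplasms benign, malignant and unspecified", 0.003),
    ("Fatigue", "General disorders and administration site conditions", 0.08),
    ("Drug ineffective", "General disorders and administration site conditions", 0.07),
    ("Condition aggravated", "General disorders and administration site conditions", 0.03),
    ("Nausea", "Gastrointestinal disorders", 0.05),
    ("Diarrhoea", "Gastrointestinal disorders", 0.04),
    ("Alanine aminotransferase increased", "Investigations", 0.006),
    ("Hypertension", "Vascular disorders", 0.015),
    ("Thrombosis", "Vascular disorders", 0.003),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.03),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.03),
)

_EXAMPLE_PLANTED: tuple[tuple[str, str, float], ...] = (
    ("fingolimod", "Macular oedema", 45.0),
    ("fingolimod", "Optic neuritis", 18.0),
    ("fingolimod", "Lymphocyte count decreased", 50.0),
    ("fingolimod", "Bradycardia", 8.0),
    ("fingolimod", "Progressive multifocal leukoencephalopathy", 30.0),
    ("siponimod", "Macular oedema", 28.0),
    ("siponimod", "Optic neuritis", 8.0),
    ("siponimod", "Lymphopenia", 30.0),
    ("siponimod", "Atrioventricular block first degree", 20.0),
    ("siponimod", "Heart rate decreased", 14.0),
    ("ozanimod", "Macular oedema", 12.0),
    ("ozanimod", "Optic neuritis", 10.0),
    ("ozanimod", "Lymphopenia", 20.0),
    ("ozanimod", "Heart rate decreased", 10.0),
)


def example_config(scale: float = 1.0, seed: int = 0) -> SyntheticConfig:
    """Study-shaped generator config; ``scale`` multiplies every cohort size."""
    cfg = SyntheticConfig(
        n_reports_per_drug={
            "fingolimod": max(1, round(4019 * scale)),
            "siponimod": max(1, round(346 * scale)),
            "ozanimod": max(1, round(234 * scale)),
        },
        n_background_reports=max(1, round(30_000 * scale)),
        pt_vocabulary=[PtEntry(*row) for row in _EXAMPLE_VOCAB],
        planted_signals=[PlantedSignal(*row) for row in _EXAMPLE_PLANTED],
        duplicate_rate=0.15,
        seed=seed,
    )
    cfg.validate()
    return cfg
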