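"""Statistical calibration experiments for the signal-detection chain.

Each function runs a self-contained simulation through the package's own
primitives and reports a calibration quantity: the algebraic ROR-vs-PRR
ordering rate on random tables, Wald-interval coverage at a known odds
ratio, and end-to-end recovery of a planted relative risk through the full
generator -> deduplication -> contingency -> criteria chain. They serve the
validation suite and the reproduction script; none of them is needed for an
ordinary analysis run.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .config import PlantedSignal, PtEntry, SyntheticConfig
from .dedup import deduplicate, select_cohort
from .disproportionality import (ContingencyTable, SignalThresholds,
                                 build_tables, compute_stats, prr_stats,
                                 ror_stats)
from .ingest import DrugDictionary
from .synthetic import sample_study, study_records

__all__ = [
    "ror_gt_prr_fraction",
    "ror_ci_coverage",
    "recovery_config",
    "planted_signal_recovery",
]


def ror_gt_prr_fraction(n_tables: int = 10_000, max_cell: int = 1000,
                        seed: int = 0) -> tuple[float, int]:
    """Fraction of random tables with ROR > 1 on which ROR > PRR also holds.

    Cells are drawn uniformly from 1..max_cell so no continuity correction
    engages. The ordering is an algebraic identity
    (ROR/PRR = d(a+b) / [b(c+d)] > 1 whenever ad > bc), so the returned
    fraction should be exactly 1. Returns (fraction, number of ROR>1 tables).
    """
    rng = np.random.default_rng(seed)
    cells = rng.integers(1, max_cell + 1, size=(n_tables, 4))
    n_gt1 = 0
    n_ok = 0
    for a, b, c, d in cells:
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        ror = ror_stats(t)[0]
        if ror <= 1:
            continue
        n_gt1 += 1
        if ror > prr_stats(t)[0]:
            n_ok += 1
    return (n_ok / n_gt1 if n_gt1 else float("nan")), n_gt1


def ror_ci_coverage(theta: float, n_sims: int = 1000, n_reports: int = 10_000,
                    p_drug: float = 0.1, p_event_comparator: float = 0.05,
                    min_a: int = 5, seed: int = 0) -> tuple[float, int]:
    """Coverage of the 95% ROR interval over multinomial tables with known OR.

    Cell probabilities are built so the population odds ratio equals
    ``theta`` exactly; each simulated database is one multinomial draw of
    ``n_reports`` reports. Only tables with a >= ``min_a`` enter the
    coverage tally. Returns (coverage, number of tables kept).
    """
    odds_c = p_event_comparator / (1 - p_event_comparator)
    odds_a = theta * odds_c
    p_a = odds_a / (1 + odds_a)
    probs = np.array([
        p_drug * p_a, p_drug * (1 - p_a),
        (1 - p_drug) * p_event_comparator,
        (1 - p_drug) * (1 - p_event_comparator),
    ])
    rng = np.random.default_rng(seed)
    tables = rng.multinomial(n_reports, probs, size=n_sims)
    kept = 0
    covered = 0
    for a, b, c, d in tables:
        if a < min_a:
            continue
        kept += 1
        _, (lo, hi), _ = ror_stats(ContingencyTable(int(a), int(b), int(c), int(d)))
        if lo <= theta <= hi:
            covered += 1
    return (covered / kept if kept else float("nan")), kept


_FILLER_VOCAB: tuple[tuple[str, str, float], ...] = (
    ("Fatigue", "General disorders and administration site conditions", 0.50),
    ("Headache", "Nervous system disorders", 0.40),
    ("Nausea", "Gastrointestinal disorders", 0.35),
    ("Dizziness", "Nervous system disorders", 0.30),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.25),
)


def recovery_config(rr: float, p_background: float = 0.01,
                    n_cohort: int = 500, n_background: int = 2000,
                    duplicate_rate: float = 0.0, seed: int = 0) -> SyntheticConfig:
    """One-target-drug study with a single planted (drug, PT) relative risk.

    The filler terms keep the no-event probability per report small, so the
    resample-until-non-empty rule barely perturbs the planted conditional
    probability.
    """
    vocab = [PtEntry("Target event", "Nervous system disorders", p_background)]
    vocab += [PtEntry(*row) for row in _FILLER_VOCAB]
    cfg = SyntheticConfig(
        n_reports_per_drug={"drugA": n_cohort},
        n_background_reports=n_background,
        pt_vocabulary=vocab,
        planted_signals=[PlantedSignal("drugA", "Target event", rr)],
        duplicate_rate=duplicate_rate,
        seed=seed,
    )
    cfg.validate()
    return cfg


def planted_signal_recovery(rr: float = 10.0, n_replicates: int = 200,
                            p_background: float = 0.01, n_cohort: int = 500,
                            n_background: int = 2000, seed: int = 0,
                            thresholds: SignalThresholds = SignalThresholds(),
                            ) -> Mapping[str, float]:
    """End-to-end planted-signal recovery through the full pipeline.

    Each replicate draws a fresh synthetic study, runs deduplication, cohort
    selection and table construction, and evaluates the planted pair.
    Reports the fraction of replicates whose 95% ROR interval contains the
    planted relative risk, the fraction where all three criteria fire, the
    fraction flagged as a signal at all, and the mean case count a.
    """
    dictionary = DrugDictionary({"druga": "drugA"})
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    ci_hits = 0
    all_criteria = 0
    signalled = 0
    a_sum = 0.0
    for s in seeds:
        cfg = recovery_config(rr, p_background, n_cohort, n_background, seed=int(s))
        study = sample_study(cfg)
        reports = deduplicate(study_records(study, dictionary))
        cohort = select_cohort(reports, "drugA")
        comparator = [r for r in reports if "drugA" not in r.canonical_ps_drugs]
        tables = build_tables(cohort, comparator, level="pt")
        t = tables.get("target event")
        if t is None:
            continue
        stats = compute_stats("target event", t, thresholds=thresholds)
        a_sum += t.a
        if stats.ror_ci95[0] <= rr <= stats.ror_ci95[1]:
            ci_hits += 1
        if stats.criteria_met == {"ROR", "PRR", "BCPNN"}:
            all_criteria += 1
        if stats.signal:
            signalled += 1
    return {
        "frac_ci_covers_rr": ci_hits / n_replicates,
        "frac_all_three_criteria": all_criteria / n_replicates,
        "frac_signalled": signalled / n_replicates,
        "mean_cases": a_sum / n_replicates,
        "n_replicates": n_replicates,
    }
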