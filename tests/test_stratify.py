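"""Organ-class profile, subgroup odds ratios, ranking and death-restricted views."""

import math

import numpy as np
import pandas as pd
import pytest

from pvsignal.dedup import Report, deduplicate, select_cohort
from pvsignal.disproportionality import build_tables, ror_stats, signal_frame
from pvsignal.ingest import DrugDictionary
from pvsignal.stratify import (SubgroupSpec, age_subgroup,
                               death_subset_signals, soc_proportions,
                               subgroup_soc_ror, top_signals)
from pvsignal.synthetic import study_records

from conftest import make_config


def make_report(i, events, age=40.0, outcomes=frozenset(), drug="fingolimod"):
    from pvsignal.dedup import age_band, classify_outcomes
    return Report(caseid=str(i), primaryid=i, fda_dt="20200101", sex="female",
                  age_years=age, age_band=age_band(age), country="US",
                  reporter="consumer", year="2020", events=list(events),
                  outcomes=set(outcomes),
                  serious_categories=classify_outcomes(outcomes),
                  canonical_ps_drugs={drug}, indication_group="Unknown")


SOC_MAP = {"PT_a": "SOC_A", "PT_b": "SOC_B", "PT_c": "SOC_B"}


class TestSocProportions:
    def test_direct_event_ratio(self):
        cohort = [make_report(i, ["PT_a"]) for i in range(30)]
        cohort += [make_report(100 + i, ["PT_b"]) for i in range(70)]
        table = soc_proportions(cohort, SOC_MAP).set_index("soc")
        assert table.loc["SOC_A", "pct"] == 30.00
        assert table.loc["SOC_B", "pct"] == 70.00

    def test_single_soc_and_unmapped_bucket(self):
        cohort = [make_report(1, ["PT_a"])]
        assert soc_proportions(cohort, SOC_MAP)["pct"].iloc[0] == 100.00
        table = soc_proportions([make_report(1, ["mystery"])], SOC_MAP)
        assert table["soc"].tolist() == ["unmapped"]

    def test_percentages_sum_to_100_on_synthetic_cohort(self, bundle):
        out, study = bundle
        dictionary = DrugDictionary.from_csv(out / "drug_dictionary.csv")
        reports = deduplicate(study_records(study, dictionary))
        cohort = select_cohort(reports, "fingolimod")
        soc_map = dict(pd.read_csv(out / "pt_soc_map.csv").values)
        table = soc_proportions(cohort, soc_map)
        assert table["pct"].sum() == pytest.approx(100.0, abs=0.05)
        assert table["n_events"].sum() == sum(len({e.casefold() for e in r.events})
                                              for r in cohort)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            soc_proportions([], SOC_MAP)


class TestSubgroupRor:
    def test_trivial_subgroup_equals_unstratified(self):
        cohort = [make_report(i, ["PT_a", "PT_b"]) for i in range(20)]
        comp = [make_report(100 + i, ["PT_b"]) for i in range(80)]
        spec = SubgroupSpec("all", lambda r: True)
        sub = subgroup_soc_ror(cohort, comp, spec, SOC_MAP).set_index("soc")
        full = build_tables(cohort, comp, level="soc", pt_to_soc=SOC_MAP)
        for soc, t in full.items():
            assert sub.loc[soc, "n"] == t.a
            assert sub.loc[soc, "ror"] == pytest.approx(ror_stats(t)[0])

    def test_zero_comparator_events_force_corrected_flag(self):
        cohort = [make_report(i, ["PT_a"]) for i in range(5)]
        comp = [make_report(100 + i, ["PT_b"]) for i in range(5)]
        sub = subgroup_soc_ror(cohort, comp, SubgroupSpec("all", lambda r: True),
                               SOC_MAP).set_index("soc")
        assert bool(sub.loc["SOC_A", "corrected"])
        assert math.isfinite(sub.loc["SOC_A", "ror"])
        # SOC_B never occurs in the cohort -> listed with the ROR absent
        assert sub.loc["SOC_B", "n"] == 0 and np.isnan(sub.loc["SOC_B", "ror"])

    def test_absent_soc_reported_with_nan_ror(self):
        cohort = [make_report(1, ["PT_a"])] * 3
        comp = [make_report(2, ["PT_a"])] * 3
        sub = subgroup_soc_ror(cohort, comp, SubgroupSpec("all", lambda r: True),
                               SOC_MAP).set_index("soc")
        assert sub.loc["SOC_B", "n"] == 0 and np.isnan(sub.loc["SOC_B", "ror"])

    def test_age_band_subgroups_partition_counts(self, bundle):
        """Per-SOC cohort counts over disjoint exhaustive age subgroups sum to
        the unstratified counts."""
        out, study = bundle
        dictionary = DrugDictionary.from_csv(out / "drug_dictionary.csv")
        reports = deduplicate(study_records(study, dictionary))
        cohort = select_cohort(reports, "fingolimod")
        comp = [r for r in reports if "fingolimod" not in r.canonical_ps_drugs]
        soc_map = dict(pd.read_csv(out / "pt_soc_map.csv").values)
        bands = ["<18", "18-44", "45-64", "65-74", ">=75", "unknown"]
        specs = [SubgroupSpec(b, lambda r, b=b: r.age_band == b) for b in bands]
        total: dict[str, int] = {}
        for spec in specs:
            try:
                sub = subgroup_soc_ror(cohort, comp, spec, soc_map)
            except ValueError:
                continue
            for row in sub.itertuples():
                total[row.soc] = total.get(row.soc, 0) + row.n
        full = build_tables(cohort, comp, level="soc", pt_to_soc=soc_map)
        assert {s: int(t.a) for s, t in full.items()} == \
               {s: n for s, n in total.items() if n > 0}

    def test_empty_subgroup_is_an_error(self):
        cohort = [make_report(1, ["PT_a"], age=30)]
        with pytest.raises(ValueError, match="no cohort reports"):
            subgroup_soc_ror(cohort, cohort, age_subgroup("<18", max_years=18),
                            SOC_MAP)


class TestTopSignals:
    def frame(self, rows):
        cols = ["event", "a", "ror", "ic", "signal"]
        df = pd.DataFrame(rows, columns=cols)
        return df

    def test_orders_by_ror_descending(self):
        df = self.frame([("hemihyperaesthesia", 3, 154.17, 6.28, True),
                         ("haemorrhagic adrenal infarction", 4, 102.78, 5.96, True)])
        out = top_signals(df.sample(frac=1, random_state=0), n=20)
        assert out["event"].tolist() == ["hemihyperaesthesia",
                                        "haemorrhagic adrenal infarction"]

    def test_filters_non_signals_and_small_counts(self):
        df = self.frame([("x", 2, 500.0, 9.9, True), ("y", 10, 5.0, 2.0, True),
                         ("z", 10, 9.0, 3.0, False)])
        assert top_signals(df)["event"].tolist() == ["y"]

    def test_ties_break_by_count_then_label(self):
        df = self.frame([("beta", 5, 10.0, 3.0, True), ("alpha", 5, 10.0, 3.0, True),
                         ("gamma", 9, 10.0, 3.0, True)])
        assert top_signals(df)["event"].tolist() == ["gamma", "alpha", "beta"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        rows = [(f"pt{i}", int(rng.integers(3, 50)), float(rng.choice([1.5, 2.5, 5.0])),
                 float(rng.normal()), True) for i in range(40)]
        df = self.frame(rows)
        expected = sorted(rows, key=lambda r: (-r[2], -r[1], r[0]))[:20]
        assert top_signals(df, n=20)["event"].tolist() == [r[0] for r in expected]


class TestDeathSubset:
    def test_no_death_reports_is_an_error(self):
        cohort = [make_report(1, ["PT_a"])]
        with pytest.raises(ValueError, match="death"):
            death_subset_signals(cohort, cohort)

    def test_pair_present_only_in_death_reports(self):
        cohort = [make_report(i, ["PT_a"], outcomes={"DE"}) for i in range(5)]
        cohort += [make_report(10 + i, ["PT_b"]) for i in range(5)]
        comp = [make_report(100 + i, ["PT_b"], outcomes={"DE"} if i < 3 else frozenset())
                for i in range(50)]
        death = death_subset_signals(cohort, comp)
        assert "pt_a" in set(death["event"])
        non_death_cohort = [r for r in cohort if "death" not in r.serious_categories]
        non_death = signal_frame(build_tables(
            non_death_cohort, [r for r in comp if "death" not in r.serious_categories]))
        assert "pt_a" not in set(non_death["event"])

    def test_death_counts_bounded_by_unrestricted(self, bundle):
        out, study = bundle
        dictionary = DrugDictionary.from_csv(out / "drug_dictionary.csv")
        reports = deduplicate(study_records(study, dictionary))
        cohort = select_cohort(reports, "fingolimod")
        comp = [r for r in reports if "fingolimod" not in r.canonical_ps_drugs]
        death = death_subset_signals(cohort, comp).set_index("event")
        full = signal_frame(build_tables(cohort, comp)).set_index("event")
        for event in death.index:
            assert death.loc[event, "a"] <= full.loc[event, "a"]
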