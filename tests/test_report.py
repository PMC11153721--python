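"""End-to-end runner: output bundle, manifest, determinism, null behaviour, CLI."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from pvsignal.cli import main as cli_main
from pvsignal.config import RunConfig
from pvsignal.report import PipelineError, run_all
from pvsignal.synthetic import generate

from conftest import make_config


@pytest.fixture(scope="module")
def run_outputs(tmp_path_factory):
    root = tmp_path_factory.mktemp("run")
    store = root / "store"
    generate(make_config(seed=31), store)
    cfg = RunConfig(store_dir=store, drugs=["fingolimod", "siponimod"],
                    drug_dictionary=store / "drug_dictionary.csv",
                    pt_soc_map=store / "pt_soc_map.csv",
                    out_dir=root / "out")
    return cfg, run_all(cfg)


def test_all_outputs_present_with_manifest_counts(run_outputs):
    cfg, out = run_outputs
    expected = {"table2.csv", "attrition.csv", "manifest.json",
                "table4_fingolimod.csv", "forest_fingolimod.csv",
                "ime_fingolimod.csv", "ime_common.csv",
                "soc_profile_fingolimod.csv"}
    assert expected <= set(out.files)
    manifest = json.loads((cfg.out_dir / "manifest.json").read_text())
    for name, meta in manifest["files"].items():
        if meta["rows"] is not None:
            assert meta["rows"] == out.row_counts[name], name
        assert (cfg.out_dir / name).stat().st_size == meta["bytes"]


def test_rerun_is_byte_identical(run_outputs, tmp_path):
    cfg, out = run_outputs
    cfg2 = RunConfig(**{**vars(cfg), "out_dir": tmp_path / "out2"})
    out2 = run_all(cfg2)
    for name in out.files:
        if name == "manifest.json":
            continue  # differs only via the config-hash (out_dir is hashed)
        assert (cfg.out_dir / name).read_bytes() == \
               (tmp_path / "out2" / name).read_bytes(), name


def test_stage_failure_names_the_stage(tmp_path):
    cfg = RunConfig(store_dir=tmp_path, drugs=["fingolimod"],
                    drug_dictionary=tmp_path, out_dir=tmp_path / "o")
    with pytest.raises(PipelineError, match="ingest"):
        run_all(cfg)


def test_null_run_false_signal_rate_matches_binomial_oracle(tmp_path):
    """Under RR = 1 everywhere, the pipeline's any-signal rate over replicates
    agrees with an independent Monte-Carlo of the criteria under the exact
    null law (independent binomial counts per arm with the non-empty
    inflation)."""
    from pvsignal.dedup import deduplicate, select_cohort
    from pvsignal.disproportionality import build_tables, signal_frame
    from pvsignal.ingest import DrugDictionary
    from pvsignal.synthetic import sample_study, study_records

    base = make_config(n_reports_per_drug={"fingolimod": 300},
                       n_background_reports=1500,
                       planted_signals=[], duplicate_rate=0.0)
    dictionary = DrugDictionary.s1pr_default()
    n_reps = 20
    any_signal = 0
    for s in range(n_reps):
        study = sample_study(base.with_seed(1000 + s))
        reports = deduplicate(study_records(study, dictionary))
        cohort = select_cohort(reports, "fingolimod")
        comp = [r for r in reports if "fingolimod" not in r.canonical_ps_drugs]
        sf = signal_frame(build_tables(cohort, comp))
        any_signal += int(sf["signal"].any())

    # independent oracle: same null law, criteria recomputed from scratch
    rng = np.random.default_rng(7)
    p = np.array([e.p_background for e in base.pt_vocabulary])
    p_tilde = p / (1 - np.prod(1 - p))
    n_coh, n_comp = 300, 1500
    hits = 0
    n_mc = 1500
    for _ in range(n_mc):
        a = rng.binomial(n_coh, p_tilde)
        c = rng.binomial(n_comp, p_tilde)
        fired = False
        for ai, ci in zip(a, c):
            if ai == 0:
                continue
            bi, di = n_coh - ai, n_comp - ci
            aa, bb, cc, dd = (ai, bi, ci, di) if min(ai, bi, ci, di) > 0 else \
                (ai + .5, bi + .5, ci + .5, di + .5)
            ror = aa * dd / (bb * cc)
            lo = math.exp(math.log(ror) - 1.96 * math.sqrt(1/aa + 1/bb + 1/cc + 1/dd))
            prr = (aa / (aa + bb)) / (cc / (cc + dd))
            nn = aa + bb + cc + dd
            chi2 = nn * (aa*dd - bb*cc) ** 2 / ((aa+bb) * (cc+dd) * (aa+cc) * (bb+dd))
            e = (aa + bb) * (aa + cc) / nn
            ic = math.log2((ai + 0.5) / (e + 0.5))
            ic025 = ic - 3.3 * (ai + 0.5) ** -0.5 - 2 * (ai + 0.5) ** -1.5
            if (ai >= 3 and lo > 1) or (ai >= 3 and prr >= 2 and chi2 >= 4) or ic025 > 0:
                fired = True
                break
        hits += fired
    p_hat = hits / n_mc
    # exact-binomial 99.9% band for the pipeline's count at the oracle rate
    from scipy.stats import binom
    lo_k, hi_k = binom.ppf(0.0005, n_reps, p_hat), binom.ppf(0.9995, n_reps, p_hat)
    assert lo_k <= any_signal <= hi_k, (any_signal, p_hat)


class TestCli:
    def test_simulate_and_signals_commands(self, tmp_path):
        config = tmp_path / "sim.toml"
        config.write_text(
            'n_background_reports = 400\n'
            'duplicate_rate = 0.2\n'
            'seed = 4\n'
            'quarter_range = ["2020Q1", "2020Q2"]\n'
            '[n_reports_per_drug]\nfingolimod = 120\n'
            '[[pt_vocabulary]]\npt = "Headache"\nsoc = "Nervous system disorders"\n'
            'p_background = 0.4\n'
            '[[pt_vocabulary]]\npt = "Macular oedema"\nsoc = "Eye disorders"\n'
            'p_background = 0.01\n'
            '[[planted_signals]]\ndrug = "fingolimod"\npt = "Macular oedema"\nrr = 20.0\n'
        )
        runner = CliRunner()
        store = tmp_path / "store"
        res = runner.invoke(cli_main, ["simulate", "--config", str(config),
                                       "--out", str(store)])
        assert res.exit_code == 0, res.output
        assert "wrote" in res.output

        out_csv = tmp_path / "signals.csv"
        res = runner.invoke(cli_main, [
            "signals", "--store", str(store), "--drug", "fingolimod",
            "--drug-dict", str(store / "drug_dictionary.csv"),
            "--out", str(out_csv)])
        assert res.exit_code == 0, res.output
        text = out_csv.read_text()
        assert "macular oedema" in text

    def test_run_command_with_toml(self, tmp_path):
        store = tmp_path / "store"
        generate(make_config(seed=8), store)
        cfg = tmp_path / "run.toml"
        cfg.write_text(
            f'store_dir = "{store}"\n'
            'drugs = ["fingolimod"]\n'
            f'drug_dictionary = "{store / "drug_dictionary.csv"}"\n'
            f'pt_soc_map = "{store / "pt_soc_map.csv"}"\n'
            f'out_dir = "{tmp_path / "out"}"\n'
        )
        res = CliRunner().invoke(cli_main, ["run", "--config", str(cfg)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "table2.csv").exists()
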