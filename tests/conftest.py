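import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from pvsignal.config import PlantedSignal, PtEntry, SyntheticConfig  # noqa: E402

SMALL_VOCAB = [
    PtEntry("Fatigue", "General disorders and administration site conditions", 0.50),
    PtEntry("Headache", "Nervous system disorders", 0.40),
    PtEntry("Nausea", "Gastrointestinal disorders", 0.35),
    PtEntry("Dizziness", "Nervous system disorders", 0.30),
    PtEntry("Rash", "Skin and subcutaneous tissue disorders", 0.25),
    PtEntry("Macular oedema", "Eye disorders", 0.002),
    PtEntry("Bradycardia", "Cardiac disorders", 0.005),
    PtEntry("Target event", "Nervous system disorders", 0.01),
]


def make_config(**overrides) -> SyntheticConfig:
    """Small two-target-drug study with one planted relative risk."""
    defaults = dict(
        n_reports_per_drug={"fingolimod": 300, "siponimod": 150},
        n_background_reports=1200,
        pt_vocabulary=SMALL_VOCAB,
        planted_signals=[PlantedSignal("fingolimod", "Target event", 10.0)],
        duplicate_rate=0.3,
        quarter_range=["2019Q1", "2019Q2", "2019Q3", "2019Q4", "2020Q1"],
        seed=12345,
    )
    defaults.update(overrides)
    cfg = SyntheticConfig(**defaults)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return make_config()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, small_config):
    """(directory, study) for a generated on-disk quarterly bundle."""
    from pvsignal.synthetic import generate

    out = tmp_path_factory.mktemp("bundle")
    study = generate(small_config, out)
    return out, study
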