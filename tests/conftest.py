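import pytest

from labharbor import dictionary as dm
from labharbor import harmonize as hz
from labharbor import synthetic as syn
from labharbor.ingest import PanelGrammar, explode_panels, parse_ehr_export


@pytest.fixture(scope="session")
def dd():
    return dm.default_mcc_dictionary()


@pytest.fixture(scope="session")
def lut(dd):
    return hz.default_lookup(dd)


@pytest.fixture(scope="session")
def small_truth():
    """A 30-subject cohort with same-day repeat draws and a real effect
    on creatinine, shared by read-only tests."""
    cfg = syn.SimulationConfig(
        n_subjects=30,
        seed=42,
        true_log_hr={"cre": 0.4},
        corruption=syn.CorruptionRates(0, 0, 0, 0.2),
    )
    return syn.simulate_cohort(cfg)


def pipeline_from_untidy(text, lut, xwalk, dd, strict=True):
    """Parse an untidy export and run the full harmonization pipeline."""
    observations, rejects = [], []
    for row in parse_ehr_export(text):
        obs, rej = explode_panels(row, PanelGrammar())
        observations.extend(obs)
        rejects.extend(rej)
    result = hz.run_pipeline(observations, lut, xwalk, dd, strict=strict)
    return result, rejects
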