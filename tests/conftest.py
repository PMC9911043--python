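import pytest

from cohortcua.cohort import EngineSettings, LifeTable
from cohortcua.config import audit_distributions
from cohortcua.survival import ParametricSurvival
from cohortcua.synth import baseline_fixture, synthetic_life_table

# Fitted progression-free / overall survival parameters (scale-rate form,
# cycle time) for the two arms.
BSC_PFS = (0.11712, 0.80840)
BSC_OS = (0.0051219, 1.3690167)
CBSC_PFS = (0.034595, 0.840056)
CBSC_OS = (0.006220, 1.070002)

WTP = 36007.0


@pytest.fixture(scope="session")
def fixture_config() -> dict:
    cfg = baseline_fixture()
    audit_distributions(cfg)
    return cfg


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return synthetic_life_table()


@pytest.fixture
def bsc_pfs() -> ParametricSurvival:
    return ParametricSurvival("loglogistic", BSC_PFS)


@pytest.fixture
def bsc_os() -> ParametricSurvival:
    return ParametricSurvival("loglogistic", BSC_OS)


@pytest.fixture
def default_settings() -> EngineSettings:
    return EngineSettings()
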