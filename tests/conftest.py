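import numpy as np
import pytest

from t2soflc.fuzzy_core.rules import RuleBase, read_rulebase
from t2soflc.soflc import fixture_path


@pytest.fixture(scope="session")
def expert_atr() -> RuleBase:
    return read_rulebase(fixture_path("expert_atracurium.csv"))


@pytest.fixture(scope="session")
def expert_iso() -> RuleBase:
    return read_rulebase(fixture_path("expert_isoflurane.csv"))


@pytest.fixture(scope="session")
def extracted_atr() -> RuleBase:
    return read_rulebase(fixture_path("extracted_atracurium.csv"))


@pytest.fixture(scope="session")
def extracted_iso() -> RuleBase:
    return read_rulebase(fixture_path("extracted_isoflurane.csv"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
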