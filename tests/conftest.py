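from __future__ import annotations

import warnings

import pytest

try:
    from hypothesis import settings

    settings.register_profile("repro", derandomize=True, max_examples=60)
    settings.load_profile("repro")
except ImportError:  # pragma: no cover
    pass

from oxplid import load_rules, parse_abbreviation, predict_oxidized_lipidome
from oxplid.config import ScoringConfig

LIPIDOME = [
    "PC(16:0/18:2)",
    "PC(16:0/20:4)",
    "PC(18:2/18:2)",
    "PE(18:0/20:4)",
    "PE(16:0/18:3)",
    "PA(18:1/20:3)",
    "PG(16:0/18:1)",
    "PS(18:0/22:6)",
]


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def cfg():
    return ScoringConfig()


@pytest.fixture(scope="session")
def lipidome():
    return [parse_abbreviation(a) for a in LIPIDOME]


@pytest.fixture(scope="session")
def predicted(lipidome, rules):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        products, errors = predict_oxidized_lipidome(lipidome, rules)
    assert not errors
    return products
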