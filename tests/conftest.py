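import pytest

from sulfoscreen.database import (
    build_aglycone_registry,
    build_moieties,
    generate_database,
)
from sulfoscreen.reference import load_reference_annotations
from sulfoscreen.rules import load_rule_library


@pytest.fixture(scope="session")
def registry():
    return build_aglycone_registry()


@pytest.fixture(scope="session")
def moieties():
    return build_moieties()


@pytest.fixture(scope="session")
def suspect_db(registry, moieties):
    return generate_database(registry, moieties)


@pytest.fixture(scope="session")
def rule_library(registry):
    return load_rule_library(registry=registry)


@pytest.fixture(scope="session")
def moiety_deltas(moieties):
    return {m.name: m.delta_formula for m in moieties}


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_annotations()
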