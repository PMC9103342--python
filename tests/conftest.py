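import pytest

import macbeth_triage as mt

SECTOR_IDS = ["sector_I", "sector_II", "sector_III", "sector_IV"]


@pytest.fixture(scope="session")
def bauru():
    return mt.load_bauru_bundle()


@pytest.fixture(scope="session")
def tree(bauru):
    return bauru.tree


@pytest.fixture(scope="session")
def typical_case():
    return mt.load_typical_case()


@pytest.fixture(scope="session")
def sector_rankings(bauru):
    return [bauru.sectors[s].ranking for s in SECTOR_IDS]


@pytest.fixture(scope="session")
def round1_responses():
    from macbeth_triage.delphi import read_responses
    from macbeth_triage.bundle import fixture_path

    return read_responses(fixture_path("bauru_delphi_round1.csv"))
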