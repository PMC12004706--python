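import pytest

from navblock.model import CellParams, DrugParams, GatingParams


@pytest.fixture(scope="session")
def gating() -> GatingParams:
    return GatingParams()


@pytest.fixture(scope="session")
def drug() -> DrugParams:
    return DrugParams()


@pytest.fixture(scope="session")
def cell() -> CellParams:
    return CellParams()
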