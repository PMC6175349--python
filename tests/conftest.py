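import sys
import warnings
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chirasieve.energetics import LJCoulombEngine, default_params
from chirasieve.fixtures import generate_fixture
from chirasieve.porelib import build_preset


@pytest.fixture(autouse=True)
def _quiet_search_warnings():
    """The multi-start search legitimately warns about discarded starts
    and achiral monomers; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def engine():
    """Internal engine with the default 12 Å cutoff (scan setting)."""
    return LJCoulombEngine()


@pytest.fixture(scope="session")
def engine_nocut():
    """Internal engine with no cutoff (complex-formation setting)."""
    return LJCoulombEngine(default_params(cutoff=None))


@pytest.fixture(scope="session")
def graphene4():
    return build_preset("graphene4")


@pytest.fixture(scope="session")
def graphene3():
    return build_preset("graphene3")


@pytest.fixture(scope="session")
def graphdiyne():
    return build_preset("graphdiyne")


@pytest.fixture(scope="session")
def co2():
    return generate_fixture("co2_like")


@pytest.fixture(scope="session")
def ch4():
    return generate_fixture("ch4_like")


@pytest.fixture(scope="session")
def chiral_probe():
    return generate_fixture("chiral_probe")
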