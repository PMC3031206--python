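import numpy as np
import pytest

from nucgeom.builder import (
    generate_nucleosome_like,
    rebuild_coordinates,
    straight_bdna_spec,
)
from nucgeom.pipeline import AnalysisConfig, analyze_duplex


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on
    # execution order
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def straight_duplex():
    return rebuild_coordinates(straight_bdna_spec("ATCGAATTCCGGATCGATCGAT"))


@pytest.fixture(scope="session")
def superhelix_spec():
    return generate_nucleosome_like(147, seed=11)


@pytest.fixture(scope="session")
def superhelix_duplex(superhelix_spec):
    return rebuild_coordinates(superhelix_spec)


@pytest.fixture(scope="session")
def superhelix_result(superhelix_duplex):
    return analyze_duplex(superhelix_duplex, AnalysisConfig())


@pytest.fixture(scope="session")
def superhelix146_result():
    duplex = rebuild_coordinates(generate_nucleosome_like(146, seed=5))
    return analyze_duplex(duplex, AnalysisConfig())
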