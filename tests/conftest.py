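import pytest

import lncnet as ln


@pytest.fixture(scope="session")
def small_fixture():
    """Default small study condition: 60 diseases, 250 genes, 500 edges."""
    return ln.generate_network(ln.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def paired_fixture():
    """lncRNA-only and integrated networks sharing one planted structure."""
    return ln.make_paired_fixture(ln.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def full_scale_paired_fixture():
    """Full-size condition: 295 lncRNAs + 801 coding genes, 214 diseases."""
    return ln.make_paired_fixture(ln.full_scale(seed=0))


@pytest.fixture(scope="session")
def small_loocv(paired_fixture):
    """Cross-validation of the small integrated fixture, computed once."""
    _, integrated, _ = paired_fixture
    return ln.loocv(integrated, ln.PropagationConfig())
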