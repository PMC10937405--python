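import pytest

from svdosage.config import AnalysisConfig
from svdosage.simulate import SimConfig, gen_pangenome


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimConfig(n_genes=150, n_svs=60, n_accessions=120, seed=11)
    return gen_pangenome(cfg)


@pytest.fixture()
def config():
    return AnalysisConfig()
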