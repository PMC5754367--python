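import pytest

from epitrio.io_formats import GeneModel, GenomicInterval
from epitrio.synthetic_data import SimulationConfig, gen_locus


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def locus(default_config):
    return gen_locus(default_config)


@pytest.fixture
def toy_trio_genes():
    """The hand-checkable trio: R1(-,100-550), F2(+,500-2000), R3(-,1900-3000)."""
    r1 = GeneModel("R1", GenomicInterval("chr1", 100, 550, "-"))
    f2 = GeneModel("F2", GenomicInterval("chr1", 500, 2000, "+"))
    r3 = GeneModel("R3", GenomicInterval("chr1", 1900, 3000, "-"))
    return [r1, f2, r3]


@pytest.fixture
def toy_island():
    return GenomicInterval("chr1", 450, 700, "+")
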