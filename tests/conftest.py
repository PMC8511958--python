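import pytest
from hypothesis import settings

from tfenrich import GeneSet, GeneUniverse, TFTargetTable, make_universe

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def tiny_universe() -> GeneUniverse:
    """Ten genes g01..g10."""
    return make_universe(10)


@pytest.fixture
def tiny_table(tiny_universe) -> TFTargetTable:
    """One TF targeting the first four genes with unit scores."""
    genes = tiny_universe.genes
    return TFTargetTable(tiny_universe, {"tfA": {g: 1.0 for g in genes[:4]}})


@pytest.fixture
def tiny_query(tiny_universe) -> GeneSet:
    """Three genes, two of which are tfA targets (k_observed = 2)."""
    genes = tiny_universe.genes
    return GeneSet("q", "", (genes[0], genes[1], genes[9]))
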