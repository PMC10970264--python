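import pytest

from plastotype.io import packaged_marker_table
from plastotype.simulate import SimulationConfig, generate_panel
from plastotype.variants import build_inventory


@pytest.fixture(scope="session")
def panel_seed1():
    """Default desk-scale synthetic panel, seed 1."""
    return generate_panel(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def inventory_seed1(panel_seed1):
    aln, gene_map, _truth = panel_seed1
    return build_inventory(aln, gene_map)


@pytest.fixture(scope="session")
def vcp_rows():
    """The packaged VCP marker table (59 published markers)."""
    return packaged_marker_table()
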