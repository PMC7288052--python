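import pytest

from betascan.pose_io import phenyl_ring_selection
from betascan.simulate import make_reference_ligand


@pytest.fixture(scope="session")
def reference_pose():
    return make_reference_ligand()


@pytest.fixture(scope="session")
def ring_selection():
    return phenyl_ring_selection(residue_index=4)
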