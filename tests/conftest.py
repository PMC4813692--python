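import numpy as np
import pytest

from xlfold.synthetic_data import (
    SimulationConfig,
    make_toy_structure,
    simulate_sda_links,
)
from xlfold.xlink_data import (
    CrossLinkMatch,
    DecoyClass,
    EndChemistry,
    ResidueSite,
)


def make_match(spectrum_id, i, j, score, decoy="TT", protein="P1", q=None):
    """Minimal PSM builder for hand-constructed fixtures."""
    return CrossLinkMatch(
        spectrum_id=spectrum_id,
        site_a=ResidueSite(protein, i, "K", EndChemistry.NHS),
        site_b=ResidueSite(protein, j, "X", EndChemistry.DIAZIRINE),
        score=score,
        decoy_class=DecoyClass(decoy),
        q_value=q,
    )


@pytest.fixture(scope="session")
def toy_sim():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def toy_bundle(toy_sim):
    structure, sequence = make_toy_structure(toy_sim)
    return structure, sequence


@pytest.fixture(scope="session")
def toy_links(toy_sim, toy_bundle):
    structure, sequence = toy_bundle
    return simulate_sda_links(structure, sequence, toy_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


TINY_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LYS A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      4  CA ASER A   3       6.000   4.000   0.000  0.50  0.00           C
ATOM      5  CA BSER A   3       6.000   9.000   0.000  0.50  0.00           C
END
"""


@pytest.fixture()
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p
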