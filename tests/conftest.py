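import numpy as np
import pytest

from oxhotspot.fixtures import generate_planted_scenario
from oxhotspot.structure import AA1_TO_3, AtomRecord, ResidueRecord


def make_residue(resnum, aa1, atoms, chain="A", icode=""):
    """Hand-built residue for geometric unit tests: atoms = {name: (x, y, z)}."""
    return ResidueRecord(
        chain,
        resnum,
        icode,
        AA1_TO_3[aa1],
        aa1,
        [AtomRecord(name, name[0], np.asarray(xyz, dtype=float)) for name, xyz in atoms.items()],
    )


@pytest.fixture(scope="session")
def scenario():
    return generate_planted_scenario()


@pytest.fixture()
def scenario_paths(scenario, tmp_path):
    (tmp_path / "structure.pdb").write_text(scenario.structure_text)
    (tmp_path / "profile.hssp").write_text(scenario.profile_text)
    (tmp_path / "sites.tsv").write_text(scenario.annotations_text)
    return {
        "pdb": tmp_path / "structure.pdb",
        "hssp": tmp_path / "profile.hssp",
        "sites": tmp_path / "sites.tsv",
        "dir": tmp_path,
    }
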