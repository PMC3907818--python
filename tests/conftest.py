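import numpy as np
import pytest

from fctraj import (
    SyntheticSpec,
    build_toy_fc,
    generate_trajectory,
)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """Noise-free toy system: (model, trajectory, ground truth)."""
    model = build_toy_fc(default_spec)
    traj, truth = generate_trajectory(model, default_spec)
    return model, traj, truth


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    """A small hand-written PDB: 4 protein atoms on two chains plus a water."""
    text = "\n".join([
        "CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1",
        "ATOM      1  N   ALA A 358       1.000   2.000   3.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A 358       2.000   2.000   3.000  1.00  0.00           C",
        "ATOM      3  CA  GLY B 358       3.000   2.500   3.000  1.00  0.00           C",
        "ATOM      4  CA  GLY B 359       4.000   2.500   3.000  1.00  0.00           C",
        "HETATM    5  O   HOH A 901       8.000   8.000   8.000  1.00  0.00           O",
        "END",
    ]) + "\n"
    path = tmp_path_factory.mktemp("toy") / "toy.pdb"
    path.write_text(text)
    return path


def make_model(positions, names=None, elements=None, chains=None,
               residues=None, bonds=(), torsions=()):
    """Quick StructureModel around bare coordinates for geometry tests."""
    from fctraj import AtomRecord, Frame, StructureModel

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    chains = chains or ["A"] * n
    residues = residues or list(range(1, n + 1))
    atoms = [
        AtomRecord(atom_id=i + 1, atom_name=names[i], element=elements[i],
                   residue_number=residues[i], residue_name="ALA",
                   chain_id=chains[i])
        for i in range(n)
    ]
    model = StructureModel(atoms, bonds, torsions)
    frame = Frame(positions)
    return model, frame
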