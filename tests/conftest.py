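import numpy as np
import pytest

from phosbind.structure_io import AtomRecord, Structure


@pytest.fixture
def three_atom_pdb(tmp_path):
    """Hand-written minimal PDB: one phosphite-like hetero residue (P, O, O)."""
    text = (
        "HETATM    1  P   PHS A  90       0.000   0.000   0.000  1.00 20.00           P\n"
        "HETATM    2  O1  PHS A  90       1.520   0.000   0.000  1.00 20.00           O\n"
        "HETATM    3  O2  PHS A  90       0.000   1.520   0.000  1.00 20.00           O\n"
        "END\n"
    )
    path = tmp_path / "three_atom.pdb"
    path.write_text(text)
    return path


def make_chain(n_res, chain_id="A", start=1, resname="ALA", spacing=3.8):
    """Straightish toy chain with one CA (and N) per residue."""
    atoms = []
    for i in range(n_res):
        num = start + i
        xyz = np.array([spacing * i, 0.1 * (i % 3), 0.05 * (i % 7)])
        atoms.append(
            AtomRecord(
                name="N", element="N", coords=xyz + [0.0, 1.0, 0.2],
                residue_name=resname, residue_number=num, chain_id=chain_id,
            )
        )
        atoms.append(
            AtomRecord(
                name="CA", element="C", coords=xyz,
                residue_name=resname, residue_number=num, chain_id=chain_id,
            )
        )
    return Structure(atoms=atoms, id=f"toy_chain_{n_res}")
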