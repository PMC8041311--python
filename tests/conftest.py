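import numpy as np
import pytest

from slidescope.structure_io import build_bdna
from slidescope.synthetic_data import ToyProteinSpec, make_toy_protein

# charged positions on one helical face (i, i+3/i+4 ladder)
Q6_POSITIONS = {2: 1, 5: 1, 9: 1, 12: 1, 16: 1, 19: 1}
Q5_POSITIONS = {2: 1, 5: 1, 9: 1, 12: 1, 16: 1}
Q4_POSITIONS = {2: 1, 5: 1, 9: 1, 12: 1}


def make_pdb(records) -> str:
    """PDB text from (chain, resnum, resname, atomname, x, y, z) tuples."""
    lines = []
    for k, (chain, resnum, resname, atom, x, y, z) in enumerate(records, start=1):
        pad_atom = f" {atom:<3s}" if len(atom) < 4 else atom
        lines.append(
            f"ATOM  {k:5d} {pad_atom} {resname:<3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {atom[0]}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_q6():
    protein, pdb = make_toy_protein(ToyProteinSpec(n_residues=20, charges=Q6_POSITIONS))
    return protein


@pytest.fixture(scope="session")
def toy_q4():
    protein, _ = make_toy_protein(ToyProteinSpec(n_residues=20, charges=Q4_POSITIONS))
    return protein


@pytest.fixture(scope="session")
def toy_neutral():
    protein, _ = make_toy_protein(ToyProteinSpec(n_residues=20))
    return protein


@pytest.fixture(scope="session")
def dna52():
    return build_bdna("GCAT" * 13)


@pytest.fixture(scope="session")
def dna20():
    return build_bdna("GCAT" * 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
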