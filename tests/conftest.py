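import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from contactatlas.synthetic import build_synthetic_topology, default_spec
from contactatlas.topology import Atom, Chain, Residue, Topology


@pytest.fixture(scope="session")
def default_topology():
    """Reference topology of the stock synthetic complex."""
    return build_synthetic_topology(default_spec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_topology(residue_plan, links=(), has_hydrogens=None, coords=None):
    """Hand-build a Topology from a compact plan.

    residue_plan: list of (chain_id, seq, resname, [(atom_name, element, xyz), ...])
    links: (serial_a, serial_b) 1-based atom serial pairs
    """
    chains: dict[str, Chain] = {}
    residues, atoms, xyz = [], [], []
    serial = 0
    for chain_id, seq, resname, atom_list in residue_plan:
        chain = chains.setdefault(chain_id, Chain(chain_id=chain_id))
        res = Residue(chain_id=chain_id, seq_number=seq, name=resname)
        ridx = len(residues)
        for name, element, pos in atom_list:
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=element, residue_index=ridx))
            res.atom_indices.append(len(atoms) - 1)
            xyz.append(pos)
        residues.append(res)
        chain.residue_indices.append(ridx)
    if has_hydrogens is None:
        has_hydrogens = any(a.element == "H" for a in atoms)
    return Topology(
        chains=list(chains.values()),
        residues=residues,
        atoms=atoms,
        covalent_links={(min(a - 1, b - 1), max(a - 1, b - 1)) for a, b in links},
        reference_coords=np.asarray(coords if coords is not None else xyz, dtype=float),
        has_hydrogens=has_hydrogens,
    )


PEPTIDE_NAG_PDB = """\
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000  11.300  10.000  1.00  0.00           C
ATOM      4  O   ALA A   1      13.200  11.400  10.000  1.00  0.00           O
ATOM      5  N   ASN A   2      15.000  10.000  10.000  1.00  0.00           N
ATOM      6  CA  ASN A   2      16.400  10.000  10.000  1.00  0.00           C
ATOM      7  CB  ASN A   2      17.000  11.300  10.000  1.00  0.00           C
ATOM      8  CG  ASN A   2      17.000  12.800  10.000  1.00  0.00           C
ATOM      9  OD1 ASN A   2      18.100  13.300  10.000  1.00  0.00           O
ATOM     10  ND2 ASN A   2      16.000  13.700  10.000  1.00  0.00           N
ATOM     11  C   ASN A   2      17.000   9.000  10.000  1.00  0.00           C
ATOM     12  O   ASN A   2      18.200   9.000  10.000  1.00  0.00           O
ATOM     13  N   ALA A   3      20.000  10.000  10.000  1.00  0.00           N
ATOM     14  CA  ALA A   3      21.400  10.000  10.000  1.00  0.00           C
ATOM     15  C   ALA A   3      22.000  11.300  10.000  1.00  0.00           C
ATOM     16  O   ALA A   3      23.200  11.400  10.000  1.00  0.00           O
TER
HETATM   17  C1  NAG B   1      16.000  15.150  10.000  1.00  0.00           C
HETATM   18  O5  NAG B   1      15.000  16.100  10.000  1.00  0.00           O
HETATM   19  C2  NAG B   1      17.300  15.900  10.000  1.00  0.00           C
HETATM   20  O3  NAG B   1      18.400  15.100  10.000  1.00  0.00           O
END
"""


@pytest.fixture
def peptide_nag_pdb(tmp_path):
    """Three-residue peptide with one GlcNAc 1.45 Å from Asn ND2."""
    p = tmp_path / "peptide_nag.pdb"
    p.write_text(PEPTIDE_NAG_PDB)
    return p


@pytest.fixture
def peptide_nag_far_pdb(tmp_path):
    """Same, but the GlcNAc C1 is ~3.5 Å from ND2 (no covalent link)."""
    replacements = {
        "HETATM   17  C1  NAG B   1      16.000  15.150  10.000":
        "HETATM   17  C1  NAG B   1      16.000  17.200  10.000",
        "HETATM   18  O5  NAG B   1      15.000  16.100  10.000":
        "HETATM   18  O5  NAG B   1      15.000  18.150  10.000",
        "HETATM   19  C2  NAG B   1      17.300  15.900  10.000":
        "HETATM   19  C2  NAG B   1      17.300  17.950  10.000",
        "HETATM   20  O3  NAG B   1      18.400  15.100  10.000":
        "HETATM   20  O3  NAG B   1      18.400  17.150  10.000",
    }
    text = PEPTIDE_NAG_PDB
    for old, new in replacements.items():
        text = text.replace(old, new)
    p = tmp_path / "peptide_nag_far.pdb"
    p.write_text(text)
    return p
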