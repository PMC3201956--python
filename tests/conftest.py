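import textwrap

import numpy as np
import pytest

from allosite import Atom, Structure


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written 3-residue PDB with an altLoc pair, a GTP HETATM and a water."""
    text = textwrap.dedent(
        """\
        ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
        ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
        ATOM      3  C   ALA A   1      10.722   6.803  -4.164  1.00 10.00           C
        ATOM      4  O   ALA A   1       9.581   7.102  -4.511  1.00 10.00           O
        ATOM      5  CB  ALA A   1      11.852   4.630  -4.717  1.00 10.00           C
        ATOM      6  N   GLY A   2      11.211   7.090  -2.960  1.00 10.00           N
        ATOM      7  CA AGLY A   2      10.421   7.791  -1.955  0.60 10.00           C
        ATOM      8  CA BGLY A   2      10.521   7.891  -1.855  0.40 10.00           C
        ATOM      9  C   GLY A   2      11.200   7.900  -0.652  1.00 10.00           C
        ATOM     10  O   GLY A   2      12.431   7.941  -0.655  1.00 10.00           O
        ATOM     11  N   SER A   3      10.480   7.960   0.465  1.00 10.00           N
        ATOM     12  CA  SER A   3      11.101   8.084   1.785  1.00 10.00           C
        ATOM     13  C   SER A   3      10.093   8.500   2.843  1.00 10.00           C
        ATOM     14  O   SER A   3       8.890   8.534   2.576  1.00 10.00           O
        ATOM     15  OG  SER A   3      12.189   9.021   1.742  1.00 10.00           O
        ATOM     16  HG  SER A   3      12.789   8.821   1.042  1.00 10.00           H
        HETATM   17  PA  GTP A 201       5.000   5.000   5.000  1.00 20.00           P
        HETATM   18  O1A GTP A 201       5.800   5.900   5.500  1.00 20.00           O
        HETATM   19  O   HOH A 301      20.000  20.000  20.000  1.00 30.00           O
        END
        """
    )
    path = tmp_path / "three_res.pdb"
    path.write_text(text)
    return path


def make_ca_structure(coords, structure_id="toy", chain="A", element="C", resname="ALA"):
    """Structure with one CA atom per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element=element,
            resname=resname,
            resid=i + 1,
            chain=chain,
            coord=tuple(coords[i]),
        )
        for i in range(len(coords))
    ]
    return Structure(id=structure_id, atoms=atoms)


@pytest.fixture
def ca_structure_factory():
    return make_ca_structure
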