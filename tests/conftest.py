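"""Shared fixtures: tiny hand-built structures and random structure factories."""

from __future__ import annotations

import numpy as np
import pytest

from gprotiface.model import Atom, Chain, ChainRoleAssignment, Residue, Structure

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.800   7.056  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.197   7.779  -5.898  1.00  0.00           O
ATOM      5  N   GLY A   2      13.330   7.110  -3.749  1.00  0.00           N
ATOM      6  CA  GLY A   2      14.434   7.997  -3.442  1.00  0.00           C
ATOM      7  C   GLY A   2      15.718   7.486  -4.072  1.00  0.00           C
ATOM      8  O   GLY A   2      16.111   6.335  -3.846  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


def residue(chain_id, seq_id, name="ALA", atoms=None, icode="", is_polymer=True):
    return Residue(chain_id, seq_id, icode, name, atoms or [], is_polymer=is_polymer)


def single_atom_residue(chain_id, seq_id, position=(0.0, 0.0, 0.0), atom_name="CA", name="ALA"):
    return residue(chain_id, seq_id, name, [Atom(atom_name, "C", position)])


def two_chain_structure(pos_a, pos_b, structure_id="pair"):
    """Two chains of one single-atom residue each, at the given positions."""
    return Structure(
        structure_id,
        [
            Chain("A", [single_atom_residue("A", 1, pos_a)]),
            Chain("B", [single_atom_residue("B", 1, pos_b)]),
        ],
    )


def random_cloud_structure(rng, n_res_a=12, n_res_b=12, box=12.0, max_atoms=3):
    """Two chains of residues with random atoms in a shared box.

    The box size is chosen so residue pair distances straddle the 4 A
    threshold, exercising both sides of the cutoff.
    """
    chains = []
    for chain_id, n_res in (("A", n_res_a), ("B", n_res_b)):
        residues = []
        for i in range(n_res):
            n_atoms = int(rng.integers(1, max_atoms + 1))
            atoms = [
                Atom(f"C{j + 1}", "C", rng.uniform(0, box, size=3))
                for j in range(n_atoms)
            ]
            residues.append(Residue(chain_id, i + 1, "", "ALA", atoms))
        chains.append(Chain(chain_id, residues))
    return Structure("cloud", chains)


CLOUD_ROLES = ChainRoleAssignment("cloud", {"A": "receptor", "B": "Galpha"})
PAIR_ROLES = ChainRoleAssignment("pair", {"A": "receptor", "B": "Galpha"})


def random_rotation(rng):
    """A uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
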