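"""Shared fixtures: tiny hand-written structures and planted toy systems."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from ternary import ResidueGroup, Topology, Trajectory
from ternary.synthetic import make_opening_double_well, make_toy_complex


@pytest.fixture()
def three_atom_pdb(tmp_path):
    """Minimal one-residue PDB with known coordinates."""
    text = textwrap.dedent("""\
        ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
        ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
        ATOM      3  CB  ALA A   1       1.500   1.500   0.000  1.00  0.00           C
        END
        """)
    path = tmp_path / "three.pdb"
    path.write_text(text)
    return path


@pytest.fixture()
def two_chain_pdb(tmp_path):
    """Two chains, two residues each, with hydrogens on the second chain."""
    text = textwrap.dedent("""\
        ATOM      1  CA  ALA A  10       0.000   0.000   0.000  1.00  0.00           C
        ATOM      2  CB  ALA A  10       1.000   0.000   0.000  1.00  0.00           C
        ATOM      3  CA  GLY A  11       3.000   0.000   0.000  1.00  0.00           C
        TER
        ATOM      4  CA  SER B   5       0.000   5.000   0.000  1.00  0.00           C
        ATOM      5  HB1 SER B   5       0.500   5.500   0.000  1.00  0.00           H
        ATOM      6  CA  LEU B   6       3.000   5.000   0.000  1.00  0.00           C
        END
        """)
    path = tmp_path / "two_chain.pdb"
    path.write_text(text)
    return path


def simple_topology(n_residues: int = 3, atoms_per_residue: int = 2) -> Topology:
    n = n_residues * atoms_per_residue
    return Topology(
        atom_ids=np.arange(n) + 1,
        atom_names=np.asarray(["CA", "CB"] * (n // 2) if atoms_per_residue == 2
                              else ["CA"] * n),
        elements=np.asarray(["C"] * n),
        residue_index=np.repeat(np.arange(n_residues), atoms_per_residue),
        residue_names=np.asarray(["ALA"] * n_residues),
        residue_ids=np.arange(n_residues) + 1,
        residue_chains=np.asarray(["A"] * n_residues),
    )


@pytest.fixture()
def line_trajectory():
    """3 residues x 2 atoms on a line, 2 identical frames."""
    top = simple_topology()
    coords = np.zeros((2, 6, 3))
    coords[:, :, 0] = np.asarray([0.0, 1.0, 4.0, 5.0, 8.0, 9.0])
    return Trajectory(topology=top, coordinates=coords, timestep=0.5)


@pytest.fixture(scope="session")
def opening_well():
    return make_opening_double_well()


@pytest.fixture(scope="session")
def planted_toy():
    """Five planted pose clusters, 20 frames each, with a contact script."""
    return make_toy_complex(
        n_receptor_residues=10,
        n_pose_clusters=5,
        frames_per_pose=20,
        contact_script={2: range(0, 60), 7: range(0, 100), 4: range(0, 50)},
        seed=11,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
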