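"""Structure/trajectory I/O, residue selection and rigid-body geometry."""

import numpy as np
import pytest

from ternary import (
    ResidueGroup,
    Trajectory,
    geometric_center,
    geometric_centers,
    read_structure,
    read_trajectory,
    superpose,
    write_structure,
    write_trajectory,
)
from ternary.config import groups_from_dict

from conftest import random_rotation, simple_topology


class TestReadStructure:
    def test_minimal_pdb(self, three_atom_pdb):
        top, coords = read_structure(three_atom_pdb)
        assert top.n_atoms == 3
        assert top.n_residues == 1
        assert list(top.atom_names) == ["N", "CA", "CB"]
        np.testing.assert_allclose(coords[1], [1.5, 0.0, 0.0], atol=1e-3)

    def test_two_chains_contiguous_residues(self, two_chain_pdb):
        top, _ = read_structure(two_chain_pdb)
        assert top.n_residues == 4
        np.testing.assert_array_equal(top.residue_index, [0, 0, 1, 2, 2, 3])
        assert list(top.residue_ids) == [10, 11, 5, 6]
        assert list(top.residue_chains) == ["A", "A", "B", "B"]

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_cross_check_independent_parser(self, two_chain_pdb):
        """Atom counts and coordinates agree with biotite's PDB reader."""
        import biotite.structure.io.pdb as bpdb

        top, coords = read_structure(two_chain_pdb)
        arr = bpdb.PDBFile.read(str(two_chain_pdb)).get_structure(model=1)
        assert top.n_atoms == arr.array_length()
        np.testing.assert_allclose(coords, arr.coord, atol=1e-3)


class TestTrajectoryIO:
    @pytest.mark.parametrize("fmt,tol", [("DCD", 1e-4), ("XTC", 1e-2)])
    def test_round_trip(self, tmp_path, fmt, tol):
        top = simple_topology()
        rng = np.random.default_rng(0)
        coords = rng.normal(50.0, 5.0, size=(5, top.n_atoms, 3))
        traj = Trajectory(topology=top, coordinates=coords, timestep=0.1)
        path = tmp_path / f"run.{fmt.lower()}"
        write_trajectory(traj, path)
        back = read_trajectory(top, path, timestep=0.1)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.coordinates, coords, atol=tol)

    def test_atom_count_mismatch(self, tmp_path):
        top = simple_topology()
        coords = np.zeros((2, top.n_atoms, 3))
        path = tmp_path / "run.dcd"
        write_trajectory(Trajectory(topology=top, coordinates=coords), path)
        with pytest.raises(ValueError, match="atoms"):
            read_trajectory(simple_topology(n_residues=5), path)

    def test_pdb_round_trip(self, tmp_path, three_atom_pdb):
        top, coords = read_structure(three_atom_pdb)
        out = tmp_path / "copy.pdb"
        write_structure(top, coords, out)
        top2, coords2 = read_structure(out)
        assert top2.n_atoms == top.n_atoms
        np.testing.assert_allclose(coords2, coords, atol=1e-3)


class TestResidueGroups:
    def test_heavy_atoms_excludes_hydrogens(self, two_chain_pdb):
        top, _ = read_structure(two_chain_pdb)
        g = ResidueGroup(name="serB", residue_indices=(2,), atom_subset_rule="heavy_atoms")
        assert len(g.atom_indices(top)) == 1
        g_all = ResidueGroup(name="serB", residue_indices=(2,), atom_subset_rule="all_atoms")
        assert len(g_all.atom_indices(top)) == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ResidueGroup(name="empty", residue_indices=())

    def test_config_mapping_author_numbering(self, two_chain_pdb):
        top, _ = read_structure(two_chain_pdb)
        spec = {"groups": {
            "chainA": {"chain": "A", "residues": [[10, 11]]},
            "chainA_no11": {"chain": "A", "residues": [[10, 11]], "exclude": [11]},
            "leu": {"resname": "LEU"},
        }}
        groups = groups_from_dict(spec, top)
        assert groups["chainA"].residue_indices == (0, 1)
        assert groups["chainA_no11"].residue_indices == (0,)
        assert groups["leu"].residue_indices == (3,)

    def test_config_unmatched_group_raises(self, two_chain_pdb):
        top, _ = read_structure(two_chain_pdb)
        with pytest.raises(ValueError):
            groups_from_dict({"groups": {"x": {"chain": "Z", "residues": [1]}}}, top)


class TestGeometricCenter:
    def test_arithmetic(self):
        top = simple_topology(n_residues=1, atoms_per_residue=2)
        # extend to 3 atoms in a single residue
        top = simple_topology(n_residues=3, atoms_per_residue=1)
        coords = np.asarray([[[0.0, 0, 0], [3.0, 0, 0], [0.0, 3, 0]]])
        traj = Trajectory(topology=top, coordinates=coords)
        g = ResidueGroup(name="all", residue_indices=(0, 1, 2), atom_subset_rule="all_atoms")
        np.testing.assert_allclose(geometric_center(traj, g, 0), [1.0, 1.0, 0.0])

    def test_single_atom_identity(self, line_trajectory):
        g = ResidueGroup(name="r0", residue_indices=(0,), atom_subset_rule="c_alpha")
        np.testing.assert_allclose(geometric_center(line_trajectory, g, 0), [0, 0, 0])

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(1)
        top = simple_topology(n_residues=25, atoms_per_residue=2)
        coords = rng.normal(size=(3, 50, 3))
        traj = Trajectory(topology=top, coordinates=coords)
        g = ResidueGroup(name="all", residue_indices=tuple(range(25)),
                         atom_subset_rule="all_atoms")
        expected = sum(coords[1, i] for i in range(50)) / 50.0
        np.testing.assert_allclose(geometric_center(traj, g, 1), expected, atol=1e-12)

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(2)
        top = simple_topology(n_residues=10, atoms_per_residue=2)
        coords = rng.normal(size=(1, 20, 3))
        g = ResidueGroup(name="all", residue_indices=tuple(range(10)),
                         atom_subset_rule="all_atoms")
        c0 = geometric_center(Trajectory(topology=top, coordinates=coords), g, 0)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        moved = coords @ R.T + t
        c1 = geometric_center(Trajectory(topology=top, coordinates=moved), g, 0)
        np.testing.assert_allclose(c1, c0 @ R.T + t, atol=1e-10)


class TestSuperpose:
    def _noisy_pair(self, seed=3, n=30):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(n, 3))
        R = random_rotation(rng)
        moved = (ref + rng.normal(0, 0.3, size=(n, 3))) @ R.T + rng.normal(size=3)
        return ref, moved

    def _traj(self, frames):
        n = frames[0].shape[0]
        top = simple_topology(n_residues=n, atoms_per_residue=1)
        return Trajectory(topology=top, coordinates=np.stack(frames))

    def test_translation_removed(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(10, 3))
        traj = self._traj([ref, ref + np.asarray([5.0, 0, 0])])
        out = superpose(traj, 0)
        np.testing.assert_allclose(out.coordinates[1], ref, atol=1e-10)

    def test_rotation_removed(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(10, 3))
        Rz = np.asarray([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        traj = self._traj([ref, ref @ Rz.T])
        out = superpose(traj, 0)
        np.testing.assert_allclose(out.coordinates[1], ref, atol=1e-10)

    def test_matches_mdanalysis_kabsch(self):
        """Post-fit RMSD agrees with MDAnalysis' independent implementation."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        ref, moved = self._noisy_pair()
        traj = self._traj([ref, moved])
        out = superpose(traj, 0)
        ours = np.sqrt(np.mean(np.sum((out.coordinates[1] - ref) ** 2, axis=1)))
        oracle = mda_rmsd(moved, ref, center=True, superposition=True)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_internal_geometry_preserved(self):
        ref, moved = self._noisy_pair(seed=6)
        traj = self._traj([ref, moved])
        out = superpose(traj, 0)
        before = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
        after = np.linalg.norm(out.coordinates[1][:, None] - out.coordinates[1][None, :], axis=2)
        np.testing.assert_allclose(after, before, atol=1e-6)

    def test_collinear_fit_atoms_rejected(self):
        line = np.stack([np.linspace(0, 9, 10), np.zeros(10), np.zeros(10)], axis=1)
        traj = self._traj([line, line])
        with pytest.raises(ValueError, match="collinear"):
            superpose(traj, 0)
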