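"""Domain types and structure/trajectory I/O shared by every analysis stage.

The in-memory model is deliberately small: a :class:`Topology` describing
atoms and their residues, a :class:`Trajectory` holding a dense
``frames x atoms x 3`` coordinate array in Angstrom, named
:class:`ResidueGroup` selections, and :class:`CVSeries` scalar time series.
File formats (PDB, DCD, XTC) are read and written through MDAnalysis; the
rest of the package never touches files directly.

All distance/angle analyses in this package follow the convention that a
"center" is the unweighted arithmetic mean of the selected atom coordinates
(no mass weighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "ResidueGroup",
    "CVSeries",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "geometric_center",
    "geometric_centers",
    "superpose",
    "kabsch_rotation",
]

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872041

#: Simulation temperature (K) used as the package-wide default.
DEFAULT_TEMPERATURE = 310.0

_SUBSET_RULES = ("all_atoms", "heavy_atoms", "c_alpha")


@dataclass(frozen=True)
class Topology:
    """Static description of the atoms of a molecular system.

    Residues are indexed internally from 0 in file order (contiguous per
    chain); ``residue_ids`` keeps the 1-based author numbering from the PDB
    so that residues can be addressed the way the literature names them
    (e.g. A161, E299 of the Gs alpha subunit).
    """

    atom_ids: np.ndarray  # (n_atoms,) int
    atom_names: np.ndarray  # (n_atoms,) str
    elements: np.ndarray  # (n_atoms,) str, "" if unknown
    residue_index: np.ndarray  # (n_atoms,) int, 0-based internal
    residue_names: np.ndarray  # (n_residues,) str
    residue_ids: np.ndarray  # (n_residues,) int, author numbering
    residue_chains: np.ndarray  # (n_residues,) str

    def __post_init__(self) -> None:
        ids = np.asarray(self.atom_ids)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("atom_ids must be unique")
        ri = np.asarray(self.residue_index)
        if ri.min(initial=0) < 0:
            raise ValueError("residue_index must be non-negative")
        if self.n_residues and ri.max(initial=-1) >= self.n_residues:
            raise ValueError("atom refers to a residue outside the topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms.

        Uses the element field when present, otherwise falls back to the
        PDB atom-name heuristic (leading digits stripped, then 'H...').
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        for i, (el, nm) in enumerate(zip(self.elements, self.atom_names)):
            if el:
                mask[i] = el.upper() != "H"
            else:
                stripped = str(nm).lstrip("0123456789 ")
                mask[i] = not stripped.upper().startswith("H")
        return mask

    def atoms_of_residues(self, residue_indices: Iterable[int]) -> np.ndarray:
        """Atom indices (topology order) belonging to the given residues."""
        wanted = np.zeros(self.n_residues, dtype=bool)
        idx = np.asarray(list(residue_indices), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_residues):
            raise IndexError("residue index outside topology")
        wanted[idx] = True
        return np.nonzero(wanted[self.residue_index])[0]

    def find_residues(
        self,
        chain: Optional[str] = None,
        resid: Optional[int] = None,
        resname: Optional[str] = None,
    ) -> np.ndarray:
        """Internal residue indices matching chain / author id / name."""
        mask = np.ones(self.n_residues, dtype=bool)
        if chain is not None:
            mask &= self.residue_chains == chain
        if resid is not None:
            mask &= self.residue_ids == resid
        if resname is not None:
            mask &= self.residue_names == resname
        return np.nonzero(mask)[0]


@dataclass(frozen=True)
class ResidueGroup:
    """A named residue selection plus an atom-subset rule.

    ``atom_subset_rule`` is one of ``all_atoms``, ``heavy_atoms`` (default;
    geometric centers are then insensitive to hydrogen placement) and
    ``c_alpha``.
    """

    name: str
    residue_indices: tuple
    atom_subset_rule: str = "heavy_atoms"

    def __post_init__(self) -> None:
        if not self.residue_indices:
            raise ValueError(f"residue group {self.name!r} is empty")
        if self.atom_subset_rule not in _SUBSET_RULES:
            raise ValueError(
                f"unknown atom_subset_rule {self.atom_subset_rule!r}; "
                f"expected one of {_SUBSET_RULES}"
            )
        object.__setattr__(
            self, "residue_indices", tuple(dict.fromkeys(int(i) for i in self.residue_indices))
        )

    def atom_indices(self, topology: Topology) -> np.ndarray:
        """Resolve the selection to atom indices of ``topology``."""
        atoms = topology.atoms_of_residues(self.residue_indices)
        if self.atom_subset_rule == "heavy_atoms":
            atoms = atoms[topology.heavy_mask()[atoms]]
        elif self.atom_subset_rule == "c_alpha":
            names = topology.atom_names[atoms]
            atoms = atoms[np.asarray([str(n) == "CA" for n in names])]
        if atoms.size == 0:
            raise ValueError(
                f"residue group {self.name!r} selects no atoms under rule "
                f"{self.atom_subset_rule!r}"
            )
        return atoms


@dataclass(frozen=True)
class Trajectory:
    """Coordinates over time plus optional GaMD boost energies.

    coordinates are Angstrom, shape ``(n_frames, n_atoms, 3)``; ``timestep``
    is the frame spacing in ns; ``boost`` (if given) is the per-frame GaMD
    boost potential dV >= 0 in kcal/mol.
    """

    topology: Topology
    coordinates: np.ndarray
    timestep: float = 1.0
    boost: Optional[np.ndarray] = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {coords.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if not self.timestep > 0:
            raise ValueError("timestep must be positive")
        object.__setattr__(self, "coordinates", coords)
        if self.boost is not None:
            boost = np.asarray(self.boost, dtype=float)
            if boost.shape != (coords.shape[0],):
                raise ValueError("boost must be one value per frame")
            if np.any(boost < 0):
                raise ValueError("GaMD boost potential must be >= 0")
            object.__setattr__(self, "boost", boost)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns (frame index times timestep)."""
        return np.arange(self.n_frames) * self.timestep


@dataclass(frozen=True)
class CVSeries:
    """A named scalar collective-variable time series.

    ``units`` must be one of ``A`` (Angstrom), ``degrees`` or ``kcal/mol``.
    """

    name: str
    values: np.ndarray
    units: str
    timestep: float = 1.0

    _UNITS = ("A", "degrees", "kcal/mol")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("CVSeries needs a 1D array with >= 1 value")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"CVSeries {self.name!r} contains non-finite values")
        if self.units not in self._UNITS:
            raise ValueError(f"units must be one of {self._UNITS}, got {self.units!r}")
        if not self.timestep > 0:
            raise ValueError("timestep must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.timestep

    @property
    def duration(self) -> float:
        """Series duration in ns (time of the last frame)."""
        return (len(self) - 1) * self.timestep


# ---------------------------------------------------------------------------
# File I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _universe_to_topology(u) -> Topology:
    atoms = u.atoms
    try:
        elements = np.asarray([str(e) for e in atoms.elements])
    except Exception:
        elements = np.asarray([""] * len(atoms))
    try:
        chains = np.asarray([str(c) for c in u.residues.segids])
    except Exception:
        chains = np.asarray([""] * len(u.residues))
    # Prefer the PDB chainID when present (a per-atom attribute in
    # MDAnalysis; take each residue's first atom).
    try:
        atom_chains = np.asarray([str(c) for c in atoms.chainIDs])
        resindices = np.asarray(atoms.resindices)
        first = np.full(len(u.residues), -1)
        for i, ri in enumerate(resindices):
            if first[ri] < 0:
                first[ri] = i
        chain_ids = np.asarray([atom_chains[f] if f >= 0 else "" for f in first])
        if any(chain_ids):
            chains = chain_ids
    except Exception:
        pass
    return Topology(
        atom_ids=np.asarray(atoms.ids, dtype=int),
        atom_names=np.asarray([str(n) for n in atoms.names]),
        elements=elements,
        residue_index=np.asarray(atoms.resindices, dtype=int),
        residue_names=np.asarray([str(n) for n in u.residues.resnames]),
        residue_ids=np.asarray(u.residues.resids, dtype=int),
        residue_chains=chains,
    )


def read_structure(path, format: str = "PDB"):
    """Read a structure file, returning ``(Topology, coordinates)``.

    ``coordinates`` has shape ``(n_atoms, 3)`` in Angstrom. Only PDB is
    supported; parse failures surface as ``ValueError`` naming the file.
    """
    import MDAnalysis as mda

    if format.upper() != "PDB":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"could not parse {path} as PDB: {exc}") from exc
    if not hasattr(u, "trajectory") or len(u.trajectory) == 0:
        raise ValueError(f"{path} contains no coordinates")
    topology = _universe_to_topology(u)
    coords = np.asarray(u.atoms.positions, dtype=float)
    return topology, coords


def read_trajectory(topology: Topology, path, format: Optional[str] = None,
                    timestep: float = 1.0) -> Trajectory:
    """Read a DCD or XTC coordinate trajectory against a known topology."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    readers = {"DCD": DCDReader, "XTC": XTCReader}
    if fmt not in readers:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    reader = readers[fmt](str(path))
    if reader.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory {path} has {reader.n_atoms} atoms but topology has "
            f"{topology.n_atoms}"
        )
    frames = []
    try:
        for i, ts in enumerate(reader):
            frames.append(np.array(ts.positions, dtype=float))
    except Exception as exc:
        raise ValueError(f"truncated/corrupt trajectory {path} at frame {len(frames)}: {exc}")
    finally:
        reader.close()
    return Trajectory(topology=topology, coordinates=np.stack(frames), timestep=timestep)


def _universe_from(topology: Topology, coordinates: np.ndarray):
    import MDAnalysis as mda

    coords = np.asarray(coordinates, dtype=np.float32)
    if coords.ndim == 2:
        coords = coords[None]
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=topology.n_residues,
        n_segments=len(set(topology.residue_chains)),
        atom_resindex=topology.residue_index,
        residue_segindex=_segindex(topology.residue_chains),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.atom_names])
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("resnames", [str(n) for n in topology.residue_names])
    u.add_TopologyAttr("resids", topology.residue_ids)
    segids = list(dict.fromkeys(str(c) for c in topology.residue_chains))
    u.add_TopologyAttr("segids", [s or "X" for s in segids])
    u.add_TopologyAttr("chainIDs", [str(topology.residue_chains[ri]) or "X"
                                    for ri in topology.residue_index])
    u.load_new(coords, order="fac")
    return u


def _segindex(chains: np.ndarray) -> np.ndarray:
    order = list(dict.fromkeys(str(c) for c in chains))
    return np.asarray([order.index(str(c)) for c in chains])


def write_structure(topology: Topology, coordinates: np.ndarray, path) -> None:
    """Write a single frame (or multi-model set) as PDB."""
    import MDAnalysis as mda

    u = _universe_from(topology, coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=len(u.trajectory) > 1) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def write_trajectory(trajectory: Trajectory, path, format: Optional[str] = None) -> None:
    """Write trajectory coordinates as DCD or XTC."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("DCD", "XTC"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    u = _universe_from(trajectory.topology, trajectory.coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=trajectory.n_atoms, format=fmt) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------


def geometric_center(trajectory: Trajectory, group: ResidueGroup, frame: int) -> np.ndarray:
    """Unweighted mean position (Angstrom) of the group's atoms at ``frame``."""
    if not -trajectory.n_frames <= frame < trajectory.n_frames:
        raise IndexError(f"frame {frame} outside trajectory of {trajectory.n_frames} frames")
    atoms = group.atom_indices(trajectory.topology)
    return trajectory.coordinates[frame, atoms].mean(axis=0)


def geometric_centers(trajectory: Trajectory, group: ResidueGroup) -> np.ndarray:
    """Per-frame geometric centers, shape ``(n_frames, 3)``."""
    atoms = group.atom_indices(trajectory.topology)
    return trajectory.coordinates[:, atoms].mean(axis=1)


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rotation matrix R and translation aligning mobile onto
    reference: ``x_aligned = (x - mobile_centroid) @ R.T + ref_centroid``.
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(1.0, s[0])


def superpose(mobile: Trajectory, reference_frame: int = 0,
              fit_group: Optional[ResidueGroup] = None) -> Trajectory:
    """Rigid-body align every frame onto ``reference_frame``.

    The rotation/translation minimising the RMSD of ``fit_group`` atoms is
    found per frame (Kabsch) and applied to all atoms, so internal geometry
    is untouched. ``fit_group=None`` fits on all atoms.
    """
    if fit_group is None:
        fit_atoms = np.arange(mobile.n_atoms)
    else:
        fit_atoms = fit_group.atom_indices(mobile.topology)
    if fit_atoms.size < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    ref = mobile.coordinates[reference_frame, fit_atoms]
    if _collinear(ref):
        raise ValueError("fit atoms are (near-)collinear; superposition is degenerate")
    out = np.empty_like(mobile.coordinates)
    for f in range(mobile.n_frames):
        R, mc, rc = kabsch_rotation(mobile.coordinates[f, fit_atoms], ref)
        out[f] = (mobile.coordinates[f] - mc) @ R.T + rc
    return replace(mobile, coordinates=out)
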