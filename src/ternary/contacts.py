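"""Persistent-contact analysis for binding pockets and protein interfaces.

A target residue is in contact with the probe group in a frame when any of
its atoms lies within the cutoff (default 3.0 A, boundary inclusive) of any
probe atom. A contact is *persistent* when it occurs in strictly more than
a fraction (default one half) of the analysed frames. Distances use heavy
atoms by default, controlled by each group's atom_subset_rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import ResidueGroup, Trajectory

__all__ = ["ContactProfile", "frame_contacts", "persistent_contacts",
           "mean_interaction_time", "interface_residue_count"]


@dataclass(frozen=True)
class ContactProfile:
    """Per-residue contact fractions for a probe/target pair."""

    residue_indices: Tuple[int, ...]
    residue_names: Tuple[str, ...]
    contact_fraction: np.ndarray
    cutoff: float
    persistence_threshold: float
    n_frames: int

    def __post_init__(self) -> None:
        frac = np.asarray(self.contact_fraction, dtype=float)
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("contact fractions must lie in [0, 1]")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "contact_fraction", frac)

    def persistent_set(self) -> Set[int]:
        """Residues in contact strictly more than the persistence threshold."""
        mask = self.contact_fraction > self.persistence_threshold
        return {r for r, m in zip(self.residue_indices, mask) if m}

    def fraction_of(self, residue_index: int) -> float:
        try:
            pos = self.residue_indices.index(residue_index)
        except ValueError:
            return 0.0
        return float(self.contact_fraction[pos])


def _prepare(trajectory: Trajectory, probe: ResidueGroup, target: ResidueGroup):
    top = trajectory.topology
    probe_atoms = probe.atom_indices(top)
    probe_res = set(probe.residue_indices)
    # self-contact exclusion: probe residues never reported as targets
    target_res = [r for r in target.residue_indices if r not in probe_res]
    if not target_res:
        raise ValueError(
            "target group has no residues outside the probe group "
            "(self-contacts are excluded)"
        )
    target_atoms_by_res = []
    for r in target_res:
        sub = ResidueGroup(name=f"res{r}", residue_indices=(r,),
                           atom_subset_rule=target.atom_subset_rule)
        target_atoms_by_res.append(sub.atom_indices(top))
    return probe_atoms, target_res, target_atoms_by_res


def frame_contacts(trajectory: Trajectory, frame: int, probe: ResidueGroup,
                   target: ResidueGroup, cutoff: float = 3.0) -> Set[int]:
    """Target residues with any atom within ``cutoff`` of any probe atom."""
    probe_atoms, target_res, target_atoms_by_res = _prepare(trajectory, probe, target)
    coords = trajectory.coordinates[frame]
    tree = cKDTree(coords[probe_atoms])
    result = set()
    for r, atoms in zip(target_res, target_atoms_by_res):
        d, _ = tree.query(coords[atoms], k=1)
        if np.min(d) <= cutoff:
            result.add(r)
    return result


def persistent_contacts(trajectory: Trajectory, probe: ResidueGroup,
                        target: ResidueGroup, cutoff: float = 3.0,
                        persistence: float = 0.5,
                        frames: Optional[Iterable[int]] = None) -> ContactProfile:
    """Contact fractions over frames; persistent = fraction strictly > persistence."""
    probe_atoms, target_res, target_atoms_by_res = _prepare(trajectory, probe, target)
    frame_list = list(range(trajectory.n_frames)) if frames is None else list(frames)
    if not frame_list:
        raise ValueError("no frames to analyse")
    counts = np.zeros(len(target_res), dtype=int)
    for f in frame_list:
        coords = trajectory.coordinates[f]
        tree = cKDTree(coords[probe_atoms])
        for i, atoms in enumerate(target_atoms_by_res):
            d, _ = tree.query(coords[atoms], k=1)
            if np.min(d) <= cutoff:
                counts[i] += 1
    names = tuple(str(trajectory.topology.residue_names[r]) for r in target_res)
    return ContactProfile(
        residue_indices=tuple(target_res),
        residue_names=names,
        contact_fraction=counts / len(frame_list),
        cutoff=cutoff,
        persistence_threshold=persistence,
        n_frames=len(frame_list),
    )


def mean_interaction_time(profile: ContactProfile,
                          subset: Optional[Iterable[int]] = None) -> float:
    """Average percentage interaction time (100 x mean contact fraction).

    Defaults to averaging over the persistent set; an explicit residue
    subset restricts it further.
    """
    residues = profile.persistent_set() if subset is None else set(subset)
    fractions = [profile.fraction_of(r) for r in residues
                 if r in profile.residue_indices]
    if not fractions:
        raise ValueError("no residues to average over")
    return 100.0 * float(np.mean(fractions))


def interface_residue_count(trajectory: Trajectory, probe: ResidueGroup,
                            target: ResidueGroup, cutoff: float = 3.0,
                            persistence: float = 0.5,
                            window: Optional[Tuple[float, float]] = None) -> int:
    """Number of persistent target residues at the probe/target interface.

    ``window`` is an inclusive time range in ns; default is all frames.
    """
    if window is None:
        frames = None
    else:
        t0, t1 = window
        times = trajectory.times
        frames = np.nonzero((times >= t0 - 1e-12) & (times <= t1 + 1e-12))[0]
        if frames.size == 0:
            raise ValueError("window contains no frames")
    profile = persistent_contacts(trajectory, probe, target, cutoff=cutoff,
                                  persistence=persistence, frames=frames)
    return len(profile.persistent_set())
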