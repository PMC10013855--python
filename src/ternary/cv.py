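"""Collective variables: center distances, interdomain angles, RMSD series.

All measurements use geometric (unweighted) centers of residue groups, in
Angstrom, and are invariant under global rigid transforms of each frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import (
    CVSeries,
    ResidueGroup,
    Trajectory,
    geometric_centers,
    kabsch_rotation,
    superpose,
)

__all__ = [
    "AngleDefinition",
    "center_distance_series",
    "interdomain_angle_series",
    "rmsd_series",
    "window_average",
]


@dataclass(frozen=True)
class AngleDefinition:
    """Angle between two domain->anchor vectors.

    Vector i runs from the geometric center of ``domain_i`` to the center of
    the single-residue ``anchor_i``. This is the construction used for the
    Gs-alpha interdomain orientation: vector 1 through the helical domain and
    residue A161, vector 2 through the Ras-like domain and residue E299.
    """

    domain1: ResidueGroup
    anchor1: ResidueGroup
    domain2: ResidueGroup
    anchor2: ResidueGroup

    def __post_init__(self) -> None:
        for anchor in (self.anchor1, self.anchor2):
            if len(anchor.residue_indices) != 1:
                raise ValueError(f"anchor {anchor.name!r} must be a single residue")


def center_distance_series(trajectory: Trajectory, group_a: ResidueGroup,
                           group_b: ResidueGroup, name: Optional[str] = None) -> CVSeries:
    """Per-frame distance (Angstrom) between two group geometric centers."""
    ca = geometric_centers(trajectory, group_a)
    cb = geometric_centers(trajectory, group_b)
    values = np.linalg.norm(ca - cb, axis=1)
    return CVSeries(
        name=name or f"{group_a.name}-{group_b.name}",
        values=values,
        units="A",
        timestep=trajectory.timestep,
    )


def interdomain_angle_series(trajectory: Trajectory, defn: AngleDefinition,
                             name: Optional[str] = None) -> CVSeries:
    """Per-frame angle (degrees, in [0, 180]) between the two domain vectors."""
    v1 = geometric_centers(trajectory, defn.anchor1) - geometric_centers(trajectory, defn.domain1)
    v2 = geometric_centers(trajectory, defn.anchor2) - geometric_centers(trajectory, defn.domain2)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    bad = np.nonzero((n1 == 0) | (n2 == 0))[0]
    if bad.size:
        raise ValueError(f"zero-length domain vector at frame {bad[0]}")
    cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    values = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return CVSeries(
        name=name or f"angle({defn.domain1.name},{defn.domain2.name})",
        values=values,
        units="degrees",
        timestep=trajectory.timestep,
    )


def rmsd_series(trajectory: Trajectory, group: ResidueGroup,
                reference: str = "first_frame", name: Optional[str] = None) -> CVSeries:
    """Least-squares-fit RMSD (Angstrom) of the group's atoms per frame.

    ``reference`` is either ``first_frame`` or ``average_structure``; for the
    latter the mean structure is computed after superposing all frames onto
    the first frame on the same group (the convention used when quoting mean
    receptor RMSD against the average structure).
    """
    atoms = group.atom_indices(trajectory.topology)
    if atoms.size < 3:
        raise ValueError("RMSD needs at least 3 atoms")
    if reference == "first_frame":
        ref = trajectory.coordinates[0, atoms]
    elif reference == "average_structure":
        aligned = superpose(trajectory, reference_frame=0, fit_group=group)
        ref = aligned.coordinates[:, atoms].mean(axis=0)
    else:
        raise ValueError("reference must be 'first_frame' or 'average_structure'")
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        mob = trajectory.coordinates[f, atoms]
        R, mc, rc = kabsch_rotation(mob, ref)
        fitted = (mob - mc) @ R.T + rc
        values[f] = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return CVSeries(
        name=name or f"rmsd({group.name})",
        values=values,
        units="A",
        timestep=trajectory.timestep,
    )


def window_average(series: CVSeries, last_ns: Optional[float] = None) -> Tuple[float, float]:
    """Mean and SD of the series over its trailing ``last_ns`` window.

    Frames with time >= duration - last_ns are included (the first in-window
    frame inclusively). ``last_ns=None`` averages the whole series.
    """
    if last_ns is None:
        window = series.values
    else:
        if last_ns <= 0:
            raise ValueError("last_ns must be positive")
        if last_ns > series.duration + series.timestep:
            raise ValueError(
                f"window of {last_ns} ns exceeds series duration {series.duration} ns"
            )
        t0 = series.duration - last_ns
        window = series.values[series.times >= t0 - 1e-12]
    if window.size == 0:
        raise ValueError("empty averaging window")
    return float(np.mean(window)), float(np.std(window))
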