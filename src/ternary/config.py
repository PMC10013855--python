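"""YAML configuration of named residue groups.

Groups are declared with PDB author numbering (1-based residue ids per
chain) and mapped onto the topology's internal 0-based residue indices
here, so selections like "the receptor without intracellular loop 3" are
plain residue-range exclusions in the config rather than code.

Schema::

    groups:
      GsalphaAH:
        chain: A
        residues: [[60, 190]]     # inclusive id ranges (or single ids)
        exclude: [[100, 110]]     # optional ranges removed from the above
        subset: heavy_atoms       # all_atoms | heavy_atoms | c_alpha
      ligand:
        resname: LIG              # alternatively select by residue name
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Union

import numpy as np
import yaml

from .core import ResidueGroup, Topology

__all__ = ["load_groups", "groups_from_dict"]


def _expand(ranges: Union[int, Sequence]) -> Set[int]:
    out: Set[int] = set()
    if isinstance(ranges, int):
        return {ranges}
    for item in ranges:
        if isinstance(item, int):
            out.add(item)
        else:
            lo, hi = item
            if hi < lo:
                raise ValueError(f"bad residue range [{lo}, {hi}]")
            out.update(range(int(lo), int(hi) + 1))
    return out


def groups_from_dict(spec: dict, topology: Topology) -> Dict[str, ResidueGroup]:
    """Resolve a parsed group specification against a topology."""
    groups: Dict[str, ResidueGroup] = {}
    for name, g in spec.get("groups", {}).items():
        subset = g.get("subset", "heavy_atoms")
        chain = g.get("chain")
        indices: List[int] = []
        if "resname" in g:
            found = topology.find_residues(chain=chain, resname=g["resname"])
            indices = [int(i) for i in found]
        else:
            wanted = _expand(g.get("residues", []))
            wanted -= _expand(g.get("exclude", []))
            if not wanted:
                raise ValueError(f"group {name!r} selects no residues")
            for rid in sorted(wanted):
                found = topology.find_residues(chain=chain, resid=rid)
                indices.extend(int(i) for i in found)
        if not indices:
            raise ValueError(f"group {name!r} matches nothing in the topology")
        groups[name] = ResidueGroup(name=name, residue_indices=tuple(indices),
                                    atom_subset_rule=subset)
    return groups


def load_groups(path, topology: Topology) -> Dict[str, ResidueGroup]:
    """Read a YAML group file and resolve it against ``topology``."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "groups" not in spec:
        raise ValueError(f"{path} must contain a top-level 'groups' mapping")
    return groups_from_dict(spec, topology)
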