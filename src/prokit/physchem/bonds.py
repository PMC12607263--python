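"""Distance-based covalent bond perception.

Two atoms are considered bonded when their separation does not exceed the
sum of their single-bond covalent radii plus a tolerance (0.45 A default),
and exceeds 0.4 A (closer pairs are treated as coordinate errors, not
bonds).  This recovers textbook connectivity for standard geometries; no
bond orders are assigned.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..constants import COVALENT_RADII, DEFAULT_COVALENT_RADIUS
from ..structure import Structure

__all__ = ["perceive_bonds"]

_MIN_BOND_DISTANCE = 0.4


def perceive_bonds(structure: Structure, tolerance: float = 0.45,
                   include_hetero: bool = True) -> list[tuple[int, int]]:
    """Return bonded atom pairs as sorted (serial_i, serial_j) tuples.

    The bond list is symmetric by construction (each pair reported once,
    smaller serial first) and contains no self-bonds.  Isolated atoms
    simply appear in no pair.
    """
    atoms = [a for res in structure.residues
             if include_hetero or not res.is_hetero
             for a in res.atoms]
    if len(atoms) < 2:
        return []
    centers = np.array([a.coords for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, DEFAULT_COVALENT_RADIUS)
                      for a in atoms])
    tree = cKDTree(centers)
    max_cut = 2 * radii.max() + tolerance
    bonds: list[tuple[int, int]] = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        d = float(np.linalg.norm(centers[i] - centers[j]))
        if _MIN_BOND_DISTANCE < d <= radii[i] + radii[j] + tolerance:
            si, sj = atoms[i].serial, atoms[j].serial
            bonds.append((min(si, sj), max(si, sj)))
    return sorted(bonds)
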