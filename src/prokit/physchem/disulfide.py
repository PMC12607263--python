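"""Cysteine sulfur-sulfur distances and disulfide bond candidates.

A disulfide bridge places the two SG atoms about 2.05 A apart; pairs within
a configurable cutoff (2.5 A default, generous enough for modelling error)
are reported as disulfide candidates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ..structure import ResidueKey, Structure

__all__ = ["sulfur_distances", "detect_disulfides", "DEFAULT_DISULFIDE_CUTOFF"]

DEFAULT_DISULFIDE_CUTOFF = 2.5

SSPair = tuple[tuple[ResidueKey, ResidueKey], float]


def sulfur_distances(structure: Structure) -> list[SSPair]:
    """All pairwise SG-SG distances between distinct cysteines, ascending."""
    sg = [(res.key, res.atom("SG").coords)
          for res in structure.polymer_residues()
          if res.res_name == "CYS" and res.atom("SG") is not None]
    pairs: list[SSPair] = []
    for (k1, c1), (k2, c2) in itertools.combinations(sg, 2):
        pairs.append(((k1, k2), float(np.linalg.norm(c1 - c2))))
    pairs.sort(key=lambda p: (p[1], p[0][0], p[0][1]))
    return pairs


def detect_disulfides(structure: Structure,
                      cutoff: float = DEFAULT_DISULFIDE_CUTOFF) -> list[SSPair]:
    """Cysteine pairs whose SG-SG distance is at most ``cutoff`` Angstroms."""
    if cutoff < 0 or math.isnan(cutoff):
        raise ValueError("cutoff must be a non-negative number")
    return [p for p in sulfur_distances(structure) if p[1] <= cutoff]
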