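"""Gasteiger partial charges by Partial Equalization of Orbital
Electronegativity (PEOE).

Electronegativity of an atom class is modelled as a quadratic in its
partial charge, chi(q) = a + b q + c q^2.  Charge is transferred across
every bond in discrete iterations: at iteration n the amount moved between
atoms i, j with chi_j > chi_i is

    dq = (chi_j - chi_i) / chi_plus(i) * (1/2)^n

where chi_plus(i) is the cation electronegativity of the *donor* (less
electronegative) atom — 20.02 for hydrogen.  The geometric damping makes
the procedure converge in a handful of iterations; six is the customary
stopping point and the default here.

The charges depend only on the bond graph and the hybridization class of
each atom, not on geometry.  Hybridization is taken from a curated table
for standard amino-acid atom names (PDB nomenclature) and otherwise
inferred from the element and bonded degree, which is reliable when
hydrogens are explicit.  Structures without hydrogens (e.g. AlphaFold
models) get charges for the atoms present, with a warning that explicit
hydrogens are recommended for quantitative use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ..constants import GASTEIGER_PARAMS, HYDROGEN_CATION_CHI
from ..structure import ResidueKey, Structure
from .bonds import perceive_bonds

__all__ = ["ChargeSet", "gasteiger_charges", "assign_hybridization"]


@dataclass
class ChargeSet:
    per_atom: dict[int, float]           # atom serial -> charge (e units)
    per_residue: dict[ResidueKey, float]
    method: str = "gasteiger"
    excluded: list[int] | None = None    # serials without parameters

    def total(self) -> float:
        return float(sum(self.per_atom.values()))


# Hybridization classes for standard amino-acid heavy atoms (PDB names).
_BACKBONE = {"N": "N.2", "CA": "C.3", "C": "C.2", "O": "O.2", "OXT": "O.3"}
_SIDECHAIN: dict[str, dict[str, str]] = {
    "ALA": {"CB": "C.3"},
    "ARG": {"CB": "C.3", "CG": "C.3", "CD": "C.3", "NE": "N.2", "CZ": "C.2",
            "NH1": "N.2", "NH2": "N.2"},
    "ASN": {"CB": "C.3", "CG": "C.2", "OD1": "O.2", "ND2": "N.2"},
    "ASP": {"CB": "C.3", "CG": "C.2", "OD1": "O.2", "OD2": "O.3"},
    "CYS": {"CB": "C.3", "SG": "S.3"},
    "GLN": {"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.2", "NE2": "N.2"},
    "GLU": {"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.2", "OE2": "O.3"},
    "GLY": {},
    "HIS": {"CB": "C.3", "CG": "C.2", "ND1": "N.2", "CD2": "C.2",
            "CE1": "C.2", "NE2": "N.2"},
    "ILE": {"CB": "C.3", "CG1": "C.3", "CG2": "C.3", "CD1": "C.3"},
    "LEU": {"CB": "C.3", "CG": "C.3", "CD1": "C.3", "CD2": "C.3"},
    "LYS": {"CB": "C.3", "CG": "C.3", "CD": "C.3", "CE": "C.3", "NZ": "N.3"},
    "MET": {"CB": "C.3", "CG": "C.3", "SD": "S.3", "CE": "C.3"},
    "PHE": {"CB": "C.3", "CG": "C.2", "CD1": "C.2", "CD2": "C.2",
            "CE1": "C.2", "CE2": "C.2", "CZ": "C.2"},
    "PRO": {"CB": "C.3", "CG": "C.3", "CD": "C.3"},
    "SER": {"CB": "C.3", "OG": "O.3"},
    "THR": {"CB": "C.3", "OG1": "O.3", "CG2": "C.3"},
    "TRP": {"CB": "C.3", "CG": "C.2", "CD1": "C.2", "CD2": "C.2", "NE1": "N.2",
            "CE2": "C.2", "CE3": "C.2", "CZ2": "C.2", "CZ3": "C.2", "CH2": "C.2"},
    "TYR": {"CB": "C.3", "CG": "C.2", "CD1": "C.2", "CD2": "C.2",
            "CE1": "C.2", "CE2": "C.2", "CZ": "C.2", "OH": "O.3"},
    "VAL": {"CB": "C.3", "CG1": "C.3", "CG2": "C.3"},
}

_HALOGENS = {"F", "CL", "BR", "I"}


def _degree_class(element: str, degree: int) -> str | None:
    if element == "H":
        return "H"
    if element == "C":
        # degree < 2 only happens without explicit hydrogens; sp3 is the
        # least-wrong default there
        return {3: "C.2", 2: "C.1"}.get(degree, "C.3")
    if element == "N":
        if degree >= 3:
            return "N.3"
        return {2: "N.2", 1: "N.1"}.get(degree)
    if element == "O":
        return "O.3" if degree >= 2 else "O.2"
    if element == "S":
        return "S.3"
    if element in _HALOGENS:
        return element
    return None


def assign_hybridization(structure: Structure,
                         bonds: list[tuple[int, int]]) -> dict[int, str | None]:
    """Gasteiger parameter class per atom serial (None = unparameterized).

    Standard amino-acid atoms are classified by name; anything else falls
    back to an element/degree heuristic over the perceived bond graph.
    """
    degree: dict[int, int] = {}
    for i, j in bonds:
        degree[i] = degree.get(i, 0) + 1
        degree[j] = degree.get(j, 0) + 1
    classes: dict[int, str | None] = {}
    for res in structure.residues:
        table = _SIDECHAIN.get(res.res_name)
        for atom in res.atoms:
            if atom.element == "H":
                classes[atom.serial] = "H"
            elif table is not None and atom.name in _BACKBONE:
                classes[atom.serial] = _BACKBONE[atom.name]
            elif table is not None and atom.name in table:
                classes[atom.serial] = table[atom.name]
            else:
                classes[atom.serial] = _degree_class(
                    atom.element, degree.get(atom.serial, 0))
    return classes


def gasteiger_charges(structure: Structure, max_iter: int = 6,
                      include_hetero: bool = True,
                      strict: bool = False) -> ChargeSet:
    """PEOE partial charges for every parameterized atom of a structure.

    Atoms whose element/hybridization has no published PEOE coefficients
    (metals, for instance) are excluded from the calculation and reported;
    with ``strict=True`` they raise instead.  Initial charges are zero
    (neutral molecule); the returned charges therefore sum to zero within
    numerical tolerance.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    bonds = perceive_bonds(structure, include_hetero=include_hetero)
    classes = assign_hybridization(structure, bonds)

    selected: list[tuple[int, str, ResidueKey]] = []
    excluded: list[int] = []
    has_hydrogen = False
    for res in structure.residues:
        if res.is_hetero and not include_hetero:
            continue
        for atom in res.atoms:
            cls = classes.get(atom.serial)
            if cls is None or (cls != "H" and cls not in GASTEIGER_PARAMS):
                excluded.append(atom.serial)
            else:
                selected.append((atom.serial, cls, res.key))
                has_hydrogen = has_hydrogen or atom.element == "H"
    if excluded:
        msg = f"atoms without PEOE parameters: serials {excluded}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (excluded from charge calculation)", stacklevel=2)
    if not has_hydrogen and any(cls != "H" for _, cls, _ in selected):
        warnings.warn(
            "structure has no hydrogen atoms; PEOE charges are computed on "
            "heavy atoms only — add explicit hydrogens for quantitative use",
            stacklevel=2,
        )

    index = {serial: k for k, (serial, _, _) in enumerate(selected)}
    params = [GASTEIGER_PARAMS[cls] if cls != "H" else GASTEIGER_PARAMS["H"]
              for _, cls, _ in selected]
    chi_plus = [HYDROGEN_CATION_CHI if cls == "H" else sum(GASTEIGER_PARAMS[cls])
                for _, cls, _ in selected]
    edge_list = [(index[i], index[j]) for i, j in bonds
                 if i in index and j in index]

    q = [0.0] * len(selected)
    for n in range(1, max_iter + 1):
        damp = 0.5 ** n
        chi = [a + b * qi + c * qi * qi for (a, b, c), qi in zip(params, q)]
        delta = [0.0] * len(q)
        for i, j in edge_list:
            if chi[j] > chi[i]:
                d = (chi[j] - chi[i]) / chi_plus[i] * damp
                delta[i] += d
                delta[j] -= d
            elif chi[i] > chi[j]:
                d = (chi[i] - chi[j]) / chi_plus[j] * damp
                delta[j] += d
                delta[i] -= d
        q = [qi + di for qi, di in zip(q, delta)]

    per_atom = {serial: q[k] for k, (serial, _, _) in enumerate(selected)}
    per_residue: dict[ResidueKey, float] = {}
    for serial, _, rkey in selected:
        per_residue[rkey] = per_residue.get(rkey, 0.0) + per_atom[serial]
    return ChargeSet(per_atom=per_atom, per_residue=per_residue,
                     method="gasteiger", excluded=excluded or None)
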