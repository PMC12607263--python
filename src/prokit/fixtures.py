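"""Synthetic structures, molecules, and annotation tables with known
analytic properties.

Every generator is deterministic given its parameters (and seed, where one
applies), uses real residue and atom names so downstream code paths (radius
lookup, titratable-site detection, bond perception) are exercised without
special-casing, and emits objects that survive PDB round-trips.  No
physical realism beyond local bond geometry is claimed.
"""

from __future__ import annotations

import numpy as np

from .annotation import SiteAnnotation
from .constants import THREE_TO_ONE
from .structure import Atom, Residue, Structure

__all__ = [
    "make_collinear_chain",
    "make_cys_pair",
    "make_toy_molecule",
    "make_synthetic_uniprot_tsv",
    "TOY_MOLECULES",
]

_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def make_collinear_chain(n: int, spacing: float = 3.8,
                         sequence: str | None = None,
                         bfactor: float = 90.0) -> Structure:
    """``n`` single-CA pseudo-residues on the x-axis at ``i * spacing``.

    The default sequence is poly-alanine; pass a one-letter-code string of
    length ``n`` to override.  Pairwise distances are exact multiples of
    the spacing, which makes network edge counts enumerable by hand.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sequence is not None and len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != n {n}")
    residues = []
    for i in range(n):
        res_name = _ONE_TO_THREE[sequence[i].upper()] if sequence else "ALA"
        atom = Atom(serial=i + 1, name="CA", element="C",
                    coords=np.array([i * spacing, 0.0, 0.0]),
                    bfactor=bfactor)
        residues.append(Residue("A", i + 1, res_name, [atom]))
    return Structure(identifier=f"collinear{n}", residues=residues)


# one cysteine with idealized local geometry (bond lengths ~standard)
_CYS_TEMPLATE = [
    ("N",  "N", (-1.458, 0.000, 0.000)),
    ("CA", "C", (0.000, 0.000, 0.000)),
    ("C",  "C", (0.550, 1.420, 0.000)),
    ("O",  "O", (1.740, 1.650, 0.150)),
    ("CB", "C", (0.510, -0.730, 1.240)),
    ("SG", "S", (0.510, -1.130, 3.005)),
]


def make_cys_pair(s_distance: float) -> Structure:
    """Two full-side-chain cysteines whose SG-SG distance is exactly
    ``s_distance`` (second residue is the first mirrored beyond the SG
    plane, so the sulfurs face each other)."""
    if s_distance <= 0:
        raise ValueError("s_distance must be positive")
    sg_z = _CYS_TEMPLATE[-1][2][2]
    mirror = 2 * sg_z + s_distance  # z -> mirror - z maps SG to SG + s_distance
    residues = []
    serial = 1
    for seq, flip in ((1, False), (2, True)):
        atoms = []
        for name, element, (x, y, z) in _CYS_TEMPLATE:
            coords = np.array([x, y, mirror - z if flip else z])
            atoms.append(Atom(serial=serial, name=name, element=element,
                              coords=coords, bfactor=90.0))
            serial += 1
        residues.append(Residue("A", seq, "CYS", atoms))
    return Structure(identifier="cys_pair", residues=residues)


# name -> list of (atom name, element, coords); ideal geometries with all
# hydrogens explicit, chosen so covalent-radius bond perception recovers
# the textbook bond graph
TOY_MOLECULES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "H2": [
        ("H1", "H", (0.000, 0.000, 0.000)),
        ("H2", "H", (0.741, 0.000, 0.000)),
    ],
    "water": [
        ("O", "O", (0.000, 0.000, 0.000)),
        ("H1", "H", (0.957, 0.000, 0.000)),
        ("H2", "H", (-0.240, 0.927, 0.000)),
    ],
    "methane": [
        ("C", "C", (0.000, 0.000, 0.000)),
        ("H1", "H", (0.629, 0.629, 0.629)),
        ("H2", "H", (0.629, -0.629, -0.629)),
        ("H3", "H", (-0.629, 0.629, -0.629)),
        ("H4", "H", (-0.629, -0.629, 0.629)),
    ],
    "ethanol": [
        ("C1", "C", (-0.748, -0.015, 0.024)),
        ("C2", "C", (0.558, 0.420, -0.573)),
        ("O", "O", (1.384, -0.682, -0.906)),
        ("H1", "H", (-1.293, -0.633, -0.695)),
        ("H2", "H", (-0.612, -0.601, 0.937)),
        ("H3", "H", (-1.324, 0.877, 0.289)),
        ("H4", "H", (0.398, 1.021, -1.479)),
        ("H5", "H", (1.122, 1.024, 0.147)),
        ("H6", "H", (1.891, -0.426, -1.684)),
    ],
}


def make_toy_molecule(name: str) -> Structure:
    """A small molecule at ideal geometry with explicit hydrogens.

    Known names: H2, water, methane, ethanol.  Emitted as a single
    one-residue structure (record type ATOM, residue name UNL) so the
    charge and bond-perception machinery treats it like any input.
    """
    if name not in TOY_MOLECULES:
        raise ValueError(
            f"unknown molecule {name!r}; choose from {sorted(TOY_MOLECULES)}"
        )
    atoms = [
        Atom(serial=i + 1, name=atom_name, element=element,
             coords=np.array(coords))
        for i, (atom_name, element, coords) in enumerate(TOY_MOLECULES[name])
    ]
    return Structure(identifier=name, residues=[Residue("A", 1, "UNL", atoms)])


_FEATURE_POOL = [
    # (uniprot key, column name, single-position?, qualifier generator)
    ("BINDING", "Binding site", True, [("ligand", ("ATP", "GTP", "Zn(2+)", "Mg(2+)"))]),
    ("ACT_SITE", "Active site", True, [("note", ("Proton acceptor", "Nucleophile"))]),
    ("MOD_RES", "Modified residue", True, [("note", ("Phosphoserine", "N6-acetyllysine"))]),
    ("REGION", "Region", False, [("note", ("Interaction region", "Linker"))]),
]

_FEATURE_TYPE_OF = {"BINDING": "binding", "ACT_SITE": "active_site",
                    "MOD_RES": "ptm", "REGION": "region"}


def make_synthetic_uniprot_tsv(
    n_proteins: int = 1,
    features_per_protein: int = 3,
    seed: int = 0,
    sequence_length: int = 200,
    inject_malformed: bool = False,
) -> tuple[str, dict[str, list[SiteAnnotation]]]:
    """UniProt-style TSV text with known ground truth.

    Returns ``(tsv_text, truth)`` where ``truth`` maps each accession to
    the exact list of annotations a correct parser must recover.  With
    ``inject_malformed=True`` one feature with an inverted range is
    appended to each Binding site cell; a correct parser skips exactly
    that feature.  Output is byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    columns = ["Entry", "Length"] + [c for _, c, _, _ in _FEATURE_POOL]
    lines = ["\t".join(columns)]
    truth: dict[str, list[SiteAnnotation]] = {}

    for p in range(n_proteins):
        accession = f"X{p + 1:05d}"
        cells = {c: [] for _, c, _, _ in _FEATURE_POOL}
        annotations: list[SiteAnnotation] = []
        for _ in range(features_per_protein):
            key, column, single, qual_spec = _FEATURE_POOL[
                int(rng.integers(len(_FEATURE_POOL)))
            ]
            start = int(rng.integers(1, max(2, sequence_length - 20)))
            end = start if single else min(start + int(rng.integers(5, 20)),
                                           sequence_length)
            qualifiers = {}
            text = f"{key} {start}" if single else f"{key} {start}..{end}"
            for qname, choices in qual_spec:
                qvalue = str(choices[int(rng.integers(len(choices)))])
                qualifiers[qname] = qvalue
                text += f'; /{qname}="{qvalue}"'
            qualifiers["uniprot_key"] = key
            cells[column].append(text + ";")
            annotations.append(
                SiteAnnotation(_FEATURE_TYPE_OF[key], start, end, qualifiers)
            )
        if inject_malformed:
            cells["Binding site"].append('BINDING 10..5; /ligand="broken";')
        row = [accession, str(sequence_length)]
        row += [" ".join(cells[c]) for _, c, _, _ in _FEATURE_POOL]
        lines.append("\t".join(row))
        truth[accession] = annotations

    return "\n".join(lines) + "\n", truth
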