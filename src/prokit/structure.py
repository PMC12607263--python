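"""PDB-format structure I/O and per-residue confidence extraction.

Structures are held in a minimal chain/residue/atom hierarchy tailored to
residue-level analysis.  Parsing of the fixed-column PDB format is delegated
to :mod:`gemmi`; writing is done directly so the column/precision contract
is explicit.  Incomplete structures (missing residues, heteroatoms) are
accepted: residue numbering is taken verbatim from the file and gaps are
allowed.
"""

from __future__ import annotations

import urllib.error
import urllib.request
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "Structure",
    "PDBParseError",
    "PDBWriteError",
    "FetchError",
    "parse_pdb",
    "write_pdb",
    "fetch_structure",
    "extract_plddt",
    "ALPHAFOLD_URL_TEMPLATE",
]

#: Default source of predicted structures: the AlphaFold database v4 model
#: file for the first fragment of a UniProt accession.
ALPHAFOLD_URL_TEMPLATE = (
    "https://alphafold.ebi.ac.uk/files/AF-{accession}-F1-model_v4.pdb"
)


class PDBParseError(ValueError):
    """Raised when PDB text cannot be turned into a Structure."""


class PDBWriteError(ValueError):
    """Raised when a Structure cannot be rendered in fixed PDB columns."""


class FetchError(RuntimeError):
    """Raised when a remote structure cannot be retrieved; carries the URL."""

    def __init__(self, url: str, reason: str):
        super().__init__(f"could not fetch structure from {url}: {reason}")
        self.url = url


class ResidueKey(NamedTuple):
    """Unique residue identifier within a structure."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"

    @classmethod
    def from_label(cls, label: str) -> "ResidueKey":
        chain, _, rest = label.partition(":")
        digits = ""
        i = 0
        if rest[:1] == "-":
            digits = "-"
            i = 1
        while i < len(rest) and rest[i].isdigit():
            digits += rest[i]
            i += 1
        return cls(chain, int(digits), rest[i:])


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        self.element = (self.element or "X").upper()


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_hetero(self) -> bool:
        return bool(self.atoms) and all(a.is_hetero for a in self.atoms)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class Structure:
    identifier: str
    residues: list[Residue] = field(default_factory=list)
    source: str = "local_file"  # one of: alphafold, custom_url, local_file

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for res in self.residues:
            if not res.atoms:
                raise ValueError(f"residue {res.key.label} has no atoms")
            if res.key in seen:
                raise ValueError(f"duplicate residue key {res.key.label}")
            seen.add(res.key)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    def polymer_residues(self) -> list[Residue]:
        """Residues that are not purely HETATM records."""
        return [r for r in self.residues if not r.is_hetero]

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (coords -> R @ x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_residues = []
        for res in self.residues:
            atoms = [
                Atom(a.serial, a.name, a.element, rotation @ a.coords + translation,
                     a.occupancy, a.bfactor, a.is_hetero)
                for a in res.atoms
            ]
            new_residues.append(
                Residue(res.chain_id, res.seq_number, res.res_name, atoms,
                        res.insertion_code)
            )
        return Structure(self.identifier, new_residues, self.source)


def _dedupe_altlocs(atoms: list[tuple[str, Atom, float]]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, tuple[float, int, Atom]] = {}
    order: list[str] = []
    for idx, (altloc, atom, occ) in enumerate(atoms):
        if atom.name not in best:
            order.append(atom.name)
            best[atom.name] = (occ, idx, atom)
        else:
            prev_occ, prev_idx, _ = best[atom.name]
            if occ > prev_occ:
                best[atom.name] = (occ, idx, atom)
    return [best[name][2] for name in order]


def parse_pdb(text: str, identifier: str = "structure",
              source: str = "local_file") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    ATOM and HETATM records are grouped into residues in file order; for
    atoms with alternate locations only the highest-occupancy conformer is
    kept.  Only the first model of a multi-model file is read.

    Raises
    ------
    PDBParseError
        If the text is empty or contains no parsable ATOM/HETATM record;
        the message names the first offending line.
    """
    if not text or not text.strip():
        raise PDBParseError("empty input: no ATOM or HETATM records")
    try:
        doc = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"unparsable PDB text: {exc}") from exc
    if len(doc) == 0 or doc[0].count_atom_sites() == 0:
        first = next(line for line in text.splitlines() if line.strip())
        raise PDBParseError(
            f"no ATOM or HETATM records found; first line was: {first!r}"
        )

    model = doc[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            is_het = res.het_flag == "H"
            raw: list[tuple[str, Atom, float]] = []
            for atom in res:
                element = atom.element.name if atom.element else "X"
                raw.append((
                    atom.altloc,
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=element,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                        is_hetero=is_het,
                    ),
                    atom.occ,
                ))
            residues.append(
                Residue(chain.name, res.seqid.num, res.name,
                        _dedupe_altlocs(raw), icode)
            )
    return Structure(identifier=identifier, residues=residues, source=source)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(structure: Structure) -> str:
    """Render a Structure as fixed-column PDB v3.3 text.

    Coordinates are written at the format's native precision (3 decimals);
    values whose rendering would overflow the 8-character coordinate
    columns raise :class:`PDBWriteError`.
    """
    lines: list[str] = []
    for res in structure.residues:
        if len(res.chain_id) > 1:
            raise PDBWriteError(
                f"chain id {res.chain_id!r} does not fit the 1-char PDB column"
            )
        if not -999 <= res.seq_number <= 9999:
            raise PDBWriteError(f"residue number {res.seq_number} overflows columns")
        for atom in res.atoms:
            x, y, z = atom.coords
            if not all(-999.999 <= v <= 9999.999 for v in (x, y, z)):
                raise PDBWriteError(
                    f"coordinate of atom {atom.serial} overflows the 8.3f column"
                )
            if not 0 <= atom.serial <= 99999:
                raise PDBWriteError(f"atom serial {atom.serial} overflows columns")
            record = "HETATM" if atom.is_hetero else "ATOM  "
            lines.append(
                f"{record}{atom.serial:>5} {_format_atom_name(atom.name, atom.element)}"
                f" {res.res_name:>3} {res.chain_id or 'A'}{res.seq_number:>4}"
                f"{res.insertion_code or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.element:>2}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def fetch_structure(accession: str, source_url_template: str | None = None,
                    timeout: float = 30.0) -> Structure:
    """Download a PDB file by UniProt accession and parse it.

    By default the AlphaFold database v4 model file is retrieved; an
    alternative source may be given as a URL template containing the
    ``{accession}`` placeholder (``file://`` URLs work for local testing).
    """
    if not accession or not accession.strip():
        raise ValueError("accession must be non-empty")
    accession = accession.strip()
    template = source_url_template or ALPHAFOLD_URL_TEMPLATE
    url = template.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            payload = resp.read().decode("utf-8", errors="replace")
    except (urllib.error.URLError, OSError, ValueError) as exc:
        raise FetchError(url, str(exc)) from exc
    try:
        structure = parse_pdb(payload, identifier=accession)
    except PDBParseError as exc:
        raise FetchError(url, f"payload is not PDB format ({exc})") from exc
    structure.source = "alphafold" if source_url_template is None else "custom_url"
    return structure


def extract_plddt(structure: Structure) -> dict[ResidueKey, float]:
    """Per-residue pLDDT from the b-factor column of a predicted structure.

    AlphaFold writes the same pLDDT value on every atom of a residue; the
    per-residue value is that shared b-factor.  Atoms disagreeing by more
    than 1e-6 trigger a warning and the mean is used.  Values outside
    [0, 100] are returned as-is with a validation warning (the file may be
    an experimental structure whose column is a true B-factor).
    """
    result: dict[ResidueKey, float] = {}
    for res in structure.residues:
        bvals = np.array([a.bfactor for a in res.atoms], dtype=float)
        if bvals.max() - bvals.min() > 1e-6:
            warnings.warn(
                f"residue {res.key.label}: atoms disagree in b-factor "
                f"(spread {bvals.max() - bvals.min():.3g}); using the mean",
                stacklevel=2,
            )
        value = float(bvals.mean())
        if not 0.0 <= value <= 100.0:
            warnings.warn(
                f"residue {res.key.label}: b-factor {value:.4g} outside [0, 100]; "
                "not a pLDDT-annotated file?",
                stacklevel=2,
            )
        result[res.key] = value
    return result
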