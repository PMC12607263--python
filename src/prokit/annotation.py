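"""UniProt annotation tables and residue-level projection.

UniProt's TSV export carries per-protein feature columns whose cells encode
positional features in the syntax::

    BINDING 46..48; /ligand="ATP"; /evidence="..."; BINDING 91; /ligand=...

This module parses those strings into :class:`SiteAnnotation` records,
projects protein-level ranges onto individual residues, and manages
user-supplied per-residue columns with length consistency checks.  Ranges
use UniProt's 1-based inclusive coordinates, which for AlphaFold models
coincide with structure residue numbering.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SiteAnnotation",
    "ResidueAnnotationTable",
    "ProteinRecord",
    "AnnotationParseError",
    "ConsistencyError",
    "parse_feature_string",
    "parse_uniprot_table",
    "project_to_residues",
    "add_custom_column",
    "FEATURE_TYPE_MAP",
]


class AnnotationParseError(ValueError):
    """Raised for structurally invalid annotation tables."""


class ConsistencyError(ValueError):
    """Raised when residue-level data disagrees with the sequence length."""


# UniProt feature key -> this package's feature_type category.
FEATURE_TYPE_MAP: dict[str, str] = {
    "BINDING": "binding",
    "ACT_SITE": "active_site",
    "MOD_RES": "ptm",
    "LIPID": "ptm",
    "CARBOHYD": "ptm",
    "CROSSLNK": "ptm",
    "REGION": "region",
    "MOTIF": "region",
    "HELIX": "secondary_structure",
    "STRAND": "secondary_structure",
    "TURN": "secondary_structure",
    "DISULFID": "other",
    "SITE": "other",
    "DOMAIN": "other",
    "DNA_BIND": "other",
}

FEATURE_TYPES = (
    "binding", "active_site", "ptm", "region", "disorder",
    "secondary_structure", "other",
)

# Identity columns of a UniProt TSV export that never carry feature syntax.
_NON_FEATURE_COLUMNS = {
    "entry", "entry name", "protein names", "gene names", "organism",
    "sequence", "length", "reviewed", "annotation",
}

_TOKEN_RE = re.compile(
    r"\b(" + "|".join(FEATURE_TYPE_MAP) + r")\s+([^;]+)"
)
_QUALIFIER_RE = re.compile(r'/([A-Za-z_0-9]+)=("([^"]*)"|[^;]+)')
_RANGE_RE = re.compile(r"^(\d+)(?:\.\.(\d+))?$")


@dataclass(frozen=True, eq=False)
class SiteAnnotation:
    """A positional protein feature over the inclusive residue range
    [start, end], 1-based; single-position features have start == end."""

    feature_type: str
    start: int
    end: int
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid range {self.start}..{self.end} (need 1 <= start <= end)"
            )

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        pos = str(self.start) if self.start == self.end else f"{self.start}-{self.end}"
        return f"{self.feature_type}:{pos}"

    def __repr__(self) -> str:  # noqa: D105
        return f"SiteAnnotation({self.label}, {self.qualifiers})"


@dataclass
class ProteinRecord:
    accession: str
    annotations: list[SiteAnnotation] = field(default_factory=list)
    sequence: str | None = None
    length: int | None = None
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _classify(key: str, qualifiers: dict[str, str]) -> tuple[str, dict[str, str]]:
    ftype = FEATURE_TYPE_MAP[key]
    quals = dict(qualifiers)
    if key == "REGION" and quals.get("note", "").strip().lower() == "disordered":
        ftype = "disorder"
    if key in ("HELIX", "STRAND", "TURN"):
        quals.setdefault("kind", key.lower())
    if key == "DISULFID":
        quals.setdefault("kind", "disulfide")
    quals.setdefault("uniprot_key", key)
    return ftype, quals


def parse_feature_string(text: str) -> tuple[list[SiteAnnotation], list[tuple[str, str]]]:
    """Parse one UniProt feature cell into annotations.

    Returns (annotations, skipped) where ``skipped`` holds (fragment, reason)
    pairs for malformed features: non-numeric or inverted ranges and
    UniProt's uncertain-position syntax (``?``, ``<``, ``>``) are skipped,
    never guessed.
    """
    annotations: list[SiteAnnotation] = []
    skipped: list[tuple[str, str]] = []
    if not text or not text.strip():
        return annotations, skipped

    matches = list(_TOKEN_RE.finditer(text))
    for i, m in enumerate(matches):
        key = m.group(1)
        range_token = m.group(2).strip()
        seg_end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        segment = text[m.start():seg_end]
        qualifiers = {
            qm.group(1): (qm.group(3) if qm.group(3) is not None
                          else qm.group(2).strip())
            for qm in _QUALIFIER_RE.finditer(segment)
        }
        rm = _RANGE_RE.match(range_token)
        if rm is None:
            skipped.append((segment.strip().rstrip(";"),
                            f"unparsable position {range_token!r}"))
            continue
        start = int(rm.group(1))
        end = int(rm.group(2)) if rm.group(2) else start
        if not 1 <= start <= end:
            skipped.append((segment.strip().rstrip(";"),
                            f"invalid range {start}..{end}"))
            continue
        ftype, quals = _classify(key, qualifiers)
        annotations.append(SiteAnnotation(ftype, start, end, quals))
    return annotations, skipped


def parse_uniprot_table(tsv_text: str) -> dict[str, ProteinRecord]:
    """Parse a UniProt TSV export into per-protein annotation records.

    The table must have a header row with an ``Entry`` column; every other
    column is scanned for feature syntax.  Malformed features are skipped
    and recorded on ``ProteinRecord.skipped`` (with a warning), never
    silently dropped.
    """
    if not tsv_text or not tsv_text.strip():
        raise AnnotationParseError("empty table")
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    entry_col = next((c for c in df.columns if c.strip().lower() == "entry"), None)
    if entry_col is None:
        raise AnnotationParseError(
            "missing header: no 'Entry' column found "
            f"(columns were {list(df.columns)!r})"
        )

    records: dict[str, ProteinRecord] = {}
    for _, row in df.iterrows():
        accession = str(row[entry_col]).strip()
        record = ProteinRecord(accession=accession)
        for col in df.columns:
            norm = col.strip().lower()
            value = row[col]
            if pd.isna(value):
                continue
            if norm == "sequence":
                record.sequence = str(value).strip()
                continue
            if norm == "length":
                try:
                    record.length = int(value)
                except ValueError:
                    pass
                continue
            if norm in _NON_FEATURE_COLUMNS:
                continue
            anns, skipped = parse_feature_string(str(value))
            record.annotations.extend(anns)
            record.skipped.extend(skipped)
        if record.length is None and record.sequence:
            record.length = len(record.sequence)
        if record.skipped:
            warnings.warn(
                f"{accession}: skipped {len(record.skipped)} malformed feature(s): "
                + "; ".join(reason for _, reason in record.skipped),
                stacklevel=2,
            )
        records[accession] = record
    return records


@dataclass
class ResidueAnnotationTable:
    """Residue-indexed annotation columns of a fixed sequence length.

    Feature columns (one per feature type) hold, at residue i (1-based),
    the list of :class:`SiteAnnotation` objects whose range covers i —
    references to the original annotations, so ranges are recoverable.
    Custom columns may hold arbitrary per-residue values.
    """

    sequence_length: int
    columns: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        for name, values in self.columns.items():
            if len(values) != self.sequence_length:
                raise ConsistencyError(
                    f"column {name!r} has {len(values)} entries, "
                    f"expected {self.sequence_length}"
                )

    def entry(self, name: str, residue_number: int):
        """Value of column ``name`` at 1-based residue position."""
        if not 1 <= residue_number <= self.sequence_length:
            raise IndexError(
                f"residue {residue_number} outside [1, {self.sequence_length}]"
            )
        return self.columns[name][residue_number - 1]

    def annotations_of(self, feature_type: str) -> list[SiteAnnotation]:
        """Unique annotations of a feature type, in first-occurrence order."""
        seen: list[SiteAnnotation] = []
        for entries in self.columns.get(feature_type, []):
            for ann in entries:
                if not any(ann is s for s in seen):
                    seen.append(ann)
        return seen

    def covered_residues(self, annotation: SiteAnnotation) -> list[int]:
        col = self.columns.get(annotation.feature_type, [])
        return [i + 1 for i, entries in enumerate(col)
                if any(a is annotation for a in entries)]


def project_to_residues(annotations: list[SiteAnnotation],
                        sequence_length: int) -> ResidueAnnotationTable:
    """Project protein-level feature ranges onto individual residues.

    Produces one column per feature type; residue i's entry lists every
    annotation whose inclusive range contains i.  An annotation extending
    past the sequence raises :class:`ConsistencyError`.
    """
    for ann in annotations:
        if ann.end > sequence_length:
            raise ConsistencyError(
                f"annotation {ann.label} ends past sequence length {sequence_length}"
            )
    types_present = []
    for ann in annotations:
        if ann.feature_type not in types_present:
            types_present.append(ann.feature_type)
    columns: dict[str, list] = {
        t: [[] for _ in range(sequence_length)] for t in types_present
    }
    for ann in annotations:
        col = columns[ann.feature_type]
        for i in range(ann.start - 1, ann.end):
            col[i].append(ann)
    return ResidueAnnotationTable(sequence_length=sequence_length, columns=columns)


def add_custom_column(table: ResidueAnnotationTable, name: str,
                      values: list) -> ResidueAnnotationTable:
    """Attach a user-supplied per-residue column; the length must equal the
    table's sequence length.  Re-adding an existing name replaces the column
    with a warning."""
    values = list(values)
    if len(values) != table.sequence_length:
        raise ConsistencyError(
            f"column {name!r}: expected {table.sequence_length} values, "
            f"got {len(values)}"
        )
    if name in table.columns:
        warnings.warn(f"column {name!r} already exists; replacing it", stacklevel=2)
    table.columns[name] = values
    return table
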