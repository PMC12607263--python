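"""Empirical pKa estimation and Henderson-Hasselbalch protonation states.

The native pKa model is deliberately simple: each titratable group starts
from its model-compound pKa and is shifted by a fixed amount when the
residue is buried (desolvation destabilizes the charged form, so burial
raises acid pKa values and lowers base pKa values).  Burial is judged by
relative SASA against the residue type's theoretical maximum.  The model
is a transparent first-order screen, not a replacement for a Poisson-
Boltzmann or machine-learned predictor; externally computed pKa tables
(e.g. PROPKA output) can be loaded through :func:`load_external_pka` and
flow through the same downstream protonation machinery.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass

from ..constants import ACIDIC_GROUPS, BASIC_GROUPS, MODEL_PKA
from ..structure import ResidueKey, Structure
from .sasa import SasaResult, relative_sasa

__all__ = [
    "SiteKey",
    "PkaSet",
    "ProtonationState",
    "naive_pka",
    "protonation_state",
    "protonated_fraction",
    "load_external_pka",
    "TITRATABLE_RESIDUES",
]

TITRATABLE_RESIDUES = ("ASP", "GLU", "HIS", "CYS", "TYR", "LYS", "ARG")

#: (residue key, group label) — group is the residue type for side chains,
#: or "N-term"/"C-term" for chain termini.
SiteKey = tuple[ResidueKey, str]


@dataclass
class PkaSet:
    per_site: dict[SiteKey, float]
    model: str = "naive_empirical"
    skipped: list[SiteKey] | None = None


@dataclass
class ProtonationState:
    pH: float
    per_site: dict[SiteKey, float]       # protonated fraction in [0, 1]
    assignment: dict[SiteKey, bool]      # fraction >= 0.5

    def fraction(self, site: SiteKey) -> float:
        return self.per_site[site]


def naive_pka(structure: Structure, sasa: SasaResult,
              burial_shift: float = 2.0,
              burial_threshold: float = 0.2,
              include_termini: bool = True) -> PkaSet:
    """Model-compound pKa with a burial shift for every titratable site.

    pKa = model value + ``burial_shift`` for buried acids (Asp, Glu, Cys,
    Tyr, C-terminus), − ``burial_shift`` for buried bases (His, Lys, Arg,
    N-terminus); a site is buried when its residue's relative SASA falls
    below ``burial_threshold``.  Titratable residues missing from the SASA
    result are skipped and reported on the returned set.
    """
    rel = relative_sasa(structure, sasa)
    per_site: dict[SiteKey, float] = {}
    skipped: list[SiteKey] = []

    def shifted(group: str, rkey: ResidueKey) -> float | None:
        base = MODEL_PKA[group]
        if rkey not in rel:
            return None
        if rel[rkey] < burial_threshold:
            if group in ACIDIC_GROUPS:
                return base + burial_shift
            if group in BASIC_GROUPS:
                return base - burial_shift
        return base

    polymer = structure.polymer_residues()
    for res in polymer:
        if res.res_name in TITRATABLE_RESIDUES:
            value = shifted(res.res_name, res.key)
            if value is None:
                skipped.append((res.key, res.res_name))
            else:
                per_site[(res.key, res.res_name)] = value

    if include_termini and polymer:
        chains: dict[str, list] = {}
        for res in polymer:
            chains.setdefault(res.chain_id, []).append(res)
        for chain_residues in chains.values():
            for res, group in ((chain_residues[0], "N-term"),
                               (chain_residues[-1], "C-term")):
                value = shifted(group, res.key)
                if value is None:
                    skipped.append((res.key, group))
                else:
                    per_site[(res.key, group)] = value

    return PkaSet(per_site=per_site, model="naive_empirical",
                  skipped=skipped or None)


def protonated_fraction(pka: float, pH: float) -> float:
    """Henderson-Hasselbalch protonated fraction 1 / (1 + 10^(pH - pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def protonation_state(pka_set: PkaSet, pH: float = 7.0) -> ProtonationState:
    """Protonated fraction and integer assignment for every titratable site.

    The fraction is exactly 0.5 when pH equals the site pKa; the integer
    assignment calls a site protonated when its fraction is >= 0.5.
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    fractions = {site: protonated_fraction(v, pH)
                 for site, v in pka_set.per_site.items()}
    assignment = {site: f >= 0.5 for site, f in fractions.items()}
    return ProtonationState(pH=pH, per_site=fractions, assignment=assignment)


def load_external_pka(csv_text: str, model: str = "external_adapter") -> PkaSet:
    """Adapter for externally computed pKa tables.

    Expects CSV with columns ``residue_number, chain, group, pka`` (header
    required).  The result plugs into :func:`protonation_state` exactly
    like the native model's output.
    """
    reader = csv.DictReader(io.StringIO(csv_text))
    required = {"residue_number", "chain", "group", "pka"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            f"external pKa CSV needs columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    per_site: dict[SiteKey, float] = {}
    for row in reader:
        key = ResidueKey(row["chain"].strip(), int(row["residue_number"]))
        per_site[(key, row["group"].strip())] = float(row["pka"])
    return PkaSet(per_site=per_site, model=model)
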