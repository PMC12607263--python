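"""Per-residue property tables and viewer color schemes.

:func:`build_property_table` assembles whatever property sets were computed
(SASA, charge, pKa, protonation, pLDDT, annotations, custom columns) into a
single pandas DataFrame with one row per structure residue; properties that
were not computed for a residue appear as NaN and are rendered as empty
fields on CSV/TSV export, never silently dropped.

:func:`make_color_scheme` turns per-residue values into hex colors for
external structure viewers: a sequential single-hue green ramp (low = pale,
high = dark) or a diverging blue-white-red ramp around a midpoint (e.g.
charge around 0, pKa around 7).  The ramps are linear interpolations
between fixed anchor colors, so the mapping is deterministic and
order-preserving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ResidueAnnotationTable
from .physchem.charges import ChargeSet
from .physchem.pka import PkaSet, ProtonationState
from .physchem.sasa import SasaResult
from .structure import ResidueKey, Structure

__all__ = ["build_property_table", "ColorScheme", "make_color_scheme",
           "MISSING_COLOR", "write_table"]

#: Neutral gray used for residues with missing values.
MISSING_COLOR = "#808080"

# sequential ramp anchors: pale green -> dark green
_SEQ_LO = (247.0, 252.0, 245.0)
_SEQ_HI = (0.0, 68.0, 27.0)
# diverging anchors: saturated blue -> white -> saturated red
_DIV_LO = (5.0, 48.0, 97.0)
_DIV_MID = (255.0, 255.0, 255.0)
_DIV_HI = (103.0, 0.0, 31.0)


def _site_column(per_site: dict, group_of: dict[ResidueKey, str]) -> dict[ResidueKey, float]:
    """Collapse (residue, group) keyed values to per-residue side-chain values."""
    out: dict[ResidueKey, float] = {}
    for (rkey, group), value in per_site.items():
        # prefer the side-chain group (named after the residue type) over termini
        if group in ("N-term", "C-term") and rkey in out:
            continue
        if group in ("N-term", "C-term") and group_of.get(rkey) is not None:
            continue
        out[rkey] = value
        group_of[rkey] = group
    return out


def build_property_table(
    structure: Structure,
    sasa: SasaResult | None = None,
    charges: ChargeSet | None = None,
    pka: PkaSet | None = None,
    protonation: ProtonationState | None = None,
    plddt: dict[ResidueKey, float] | None = None,
    annotations: ResidueAnnotationTable | None = None,
    custom: dict[str, dict[ResidueKey, object]] | None = None,
) -> pd.DataFrame:
    """One row per residue; a column per property that was supplied.

    All property inputs must be keyed to residues of ``structure``; keys
    referring to residues the structure does not contain raise ValueError
    (they indicate the inputs came from a different structure).
    """
    res_keys = [res.key for res in structure.residues]
    key_set = set(res_keys)

    def check_keys(name: str, keys) -> None:
        alien = [k for k in keys if k not in key_set]
        if alien:
            raise ValueError(
                f"{name} refers to residues not in structure "
                f"{structure.identifier!r}: {[k.label for k in alien[:5]]}"
            )

    data: dict[str, list] = {
        "chain": [k.chain_id for k in res_keys],
        "seq_number": [k.seq_number for k in res_keys],
        "insertion_code": [k.insertion_code for k in res_keys],
        "res_name": [r.res_name for r in structure.residues],
        "is_hetero": [r.is_hetero for r in structure.residues],
    }

    if sasa is not None:
        check_keys("SASA result", sasa.per_residue)
        data["sasa_A2"] = [sasa.per_residue.get(k, math.nan) for k in res_keys]
    if charges is not None:
        check_keys("charge set", charges.per_residue)
        data["charge"] = [charges.per_residue.get(k, math.nan) for k in res_keys]
    if pka is not None:
        group_of: dict[ResidueKey, str] = {}
        col = _site_column(pka.per_site, group_of)
        check_keys("pKa set", col)
        data["pka"] = [col.get(k, math.nan) for k in res_keys]
        data["titratable_group"] = [group_of.get(k, "") for k in res_keys]
    if protonation is not None:
        col = _site_column(protonation.per_site, {})
        check_keys("protonation state", col)
        data["protonated_fraction"] = [col.get(k, math.nan) for k in res_keys]
    if plddt is not None:
        check_keys("pLDDT mapping", plddt)
        data["plddt"] = [plddt.get(k, math.nan) for k in res_keys]
    if annotations is not None:
        for ftype, column in annotations.columns.items():
            values = []
            for k in res_keys:
                if 1 <= k.seq_number <= annotations.sequence_length:
                    entry = column[k.seq_number - 1]
                    if isinstance(entry, list):
                        values.append(len(entry) > 0)
                    else:
                        values.append(entry)
                else:
                    values.append(math.nan)
            data[f"ann_{ftype}"] = values
    if custom is not None:
        for name, mapping in custom.items():
            check_keys(f"custom column {name!r}", mapping)
            data[name] = [mapping.get(k, math.nan) for k in res_keys]

    return pd.DataFrame(data)


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a property table as CSV or TSV depending on the extension.

    Missing values are rendered as empty fields.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False, na_rep="")


@dataclass
class ColorScheme:
    """Per-residue hex colors plus the value range they encode."""

    per_residue: dict[ResidueKey, str]
    value_range: tuple[float, float]
    palette: str
    midpoint: float | None = None


def _hex(rgb: tuple[float, float, float]) -> str:
    r, g, b = (int(round(max(0.0, min(255.0, c)))) for c in rgb)
    return f"#{r:02x}{g:02x}{b:02x}"


def _lerp(lo, hi, t: float) -> tuple[float, float, float]:
    return tuple(a + (b - a) * t for a, b in zip(lo, hi))


def make_color_scheme(values: dict[ResidueKey, float],
                      palette: str = "sequential",
                      midpoint: float | None = None) -> ColorScheme:
    """Map per-residue values to hex colors.

    ``sequential`` maps [min, max] linearly onto a green intensity ramp;
    ``diverging`` maps values below/above ``midpoint`` onto blue/red ramps
    with white at the midpoint (midpoint defaults to the centre of the
    value range).  Missing (None/NaN) values get a neutral gray; a constant
    column maps every residue to the ramp midpoint color.
    """
    if palette not in ("sequential", "diverging"):
        raise ValueError(f"unknown palette {palette!r}")
    finite = {k: float(v) for k, v in values.items()
              if v is not None and math.isfinite(float(v))}
    if not finite:
        raise ValueError("no non-missing values to build a color scheme from")
    vmin = min(finite.values())
    vmax = max(finite.values())
    constant = vmax == vmin

    if palette == "diverging" and midpoint is None:
        midpoint = 0.5 * (vmin + vmax)

    colors: dict[ResidueKey, str] = {}
    for key, value in values.items():
        if key not in finite:
            colors[key] = MISSING_COLOR
            continue
        v = finite[key]
        if palette == "sequential":
            t = 0.5 if constant else (v - vmin) / (vmax - vmin)
            colors[key] = _hex(_lerp(_SEQ_LO, _SEQ_HI, t))
        else:
            span_lo = midpoint - vmin
            span_hi = vmax - midpoint
            if constant and v == midpoint:
                colors[key] = _hex(_DIV_MID)
            elif v < midpoint:
                t = (midpoint - v) / span_lo if span_lo > 0 else 1.0
                colors[key] = _hex(_lerp(_DIV_MID, _DIV_LO, min(t, 1.0)))
            else:
                t = (v - midpoint) / span_hi if span_hi > 0 else (0.0 if v == midpoint else 1.0)
                colors[key] = _hex(_lerp(_DIV_MID, _DIV_HI, min(t, 1.0)))
    return ColorScheme(per_residue=colors, value_range=(vmin, vmax),
                       palette=palette, midpoint=midpoint)
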