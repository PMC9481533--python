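"""Shipped parameter tables: van der Waals radii, ligand names, ring atoms.

All tables live as editable TSV files under ``fibrilstab/data`` so that every
area- or energy-dependent result is reproducible under one declared set.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

#: Residue names treated as ligands by default. EGC/KDH are chemical-component
#: ids used for epigallocatechin gallate in deposited models; LIG is the
#: package's mock tri-ring ligand.
DEFAULT_LIGAND_NAMES = frozenset({"EGC", "KDH", "LIG"})

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


def _data_path(name: str) -> Path:
    return Path(resources.files("fibrilstab").joinpath("data", name))


def load_radius_table(path: str | Path | None = None) -> dict[str, float]:
    """Element symbol (upper-case) -> van der Waals radius in Angstrom."""
    path = Path(path) if path else _data_path("vdw_radii.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(e).upper(): float(r) for e, r in zip(df["element"], df["radius"])}


def load_ring_table(path: str | Path | None = None) -> dict[str, dict[str, list[str]]]:
    """Residue name -> {ring label -> atom-name list} for stacking metrics."""
    path = Path(path) if path else _data_path("ligand_rings.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    table: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        table.setdefault(row["residue"], {})[row["ring"]] = row["atoms"].split(",")
    return table


_TWO_LETTER = {"CL", "BR", "SE", "FE", "ZN", "MG", "MN", "NA", "CA"}


def infer_element(atom_name: str, res_name: str = "") -> str:
    """Best-effort element from an atom name when the file omits it.

    Protein/nucleic atom names start with the element letter; two-letter
    elements are recognized only for names that are exactly the symbol
    (so residue "CA" calcium vs atom "CA" alpha-carbon stays unambiguous).
    """
    name = atom_name.strip().upper()
    if not name:
        return ""
    if name in _TWO_LETTER and res_name.strip().upper() == name:
        return name
    stripped = name.lstrip("0123456789")
    if stripped[:2] in {"CL", "BR"} and res_name.strip().upper() not in _WATER_NAMES:
        # halogens appear in ligands with names like CL1
        if len(stripped) == 2 or stripped[2:].isdigit():
            return stripped[:2]
    return stripped[0] if stripped else ""


def is_water(res_name: str) -> bool:
    return res_name.strip().upper() in _WATER_NAMES
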