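"""Solvation free-energy stability maps for amyloid fibrils.

The stability metric of this package: for each heavy atom of a central chain
inside the fibril, the solvent-accessible area it buries on going from an
isolated extended reference strand to the folded fibril is multiplied by an
atomic solvation parameter (ASP, cal/mol/A^2) for the atom's class. Burying
hydrophobic (positive-ASP) surface is favorable, burying charged surface is
costly. A per-residue ordering-entropy penalty is added, and sums over atoms
and residues give residue- and chain-level stabilities in kcal/mol.

Sign convention (recorded in every output's metadata): energies are reported
as ``ASP * (SASA_fold - SASA_ref) / 1000`` so that *negative means
stabilizing* — a deeply buried Leu side chain is negative, a buried Lys
amine is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import params
from .errors import ContextError, PairingError
from .sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    compute_sasa,
    reference_sasa,
)
from .structure import FibrilStructure, write_structure

_DATA = Path(__file__).parent / "data"

SIGN_CONVENTION = "fold-minus-ref (negative = stabilizing)"


@dataclass(frozen=True)
class ASPTable:
    """Atom-class -> atomic solvation parameter in cal/mol/A^2."""

    values: dict
    table_id: str = "eisenberg-mclachlan"

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ASPTable":
        p = Path(path) if path else _DATA / "asp.tsv"
        df = pd.read_csv(p, sep="\t", comment="#")
        vals = {str(c): float(v) for c, v in zip(df["class"], df["asp"])}
        return cls(values=vals, table_id=p.stem if path else "eisenberg-mclachlan")

    def __getitem__(self, cls_name: str) -> float:
        return self.values[cls_name]


@dataclass(frozen=True)
class EntropyTable:
    """Residue name -> ordering penalty in kcal/mol (>= 0)."""

    values: dict
    table_id: str = "sidechain-tds"

    @classmethod
    def load(cls, path: str | Path | None = None) -> "EntropyTable":
        p = Path(path) if path else _DATA / "entropy.tsv"
        df = pd.read_csv(p, sep="\t", comment="#")
        vals = {str(r): float(v) for r, v in zip(df["residue"], df["penalty"])}
        if any(v < 0 for v in vals.values()):
            raise ValueError("entropy penalties must be >= 0")
        return cls(values=vals, table_id=p.stem if path else "sidechain-tds")

    def penalty(self, res_name: str) -> float:
        return self.values.get(res_name.upper(), 0.0)


# charged heavy atoms under the deterministic (no-pKa) rule
_ANIONIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CATIONIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_HIS_CATIONIC = {("HIS", "ND1"), ("HIS", "NE2")}


def classify_atom(
    res_name: str, atom_name: str, element: str, protonated_his: bool = False
) -> str | None:
    """Map a heavy atom to its solvation class; None = not parameterized.

    Carboxylate oxygens of Asp/Glu and the C-terminal OXT are charged O-;
    Lys NZ and the Arg guanidinium nitrogens are charged N+ (His ring
    nitrogens too, when the protonation flag is set); everything else falls
    to its element class.
    """
    res = res_name.upper()
    name = atom_name.upper()
    el = element.upper()
    if el == "C":
        return "C"
    if el == "S":
        return "S"
    if el == "O":
        if (res, name) in _ANIONIC or name == "OXT":
            return "O-"
        return "N/O"
    if el == "N":
        if (res, name) in _CATIONIC:
            return "N+"
        if protonated_his and (res, name) in _HIS_CATIONIC:
            return "N+"
        return "N/O"
    return None


def atom_energy(sasa_ref: float, sasa_fold: float, asp: float) -> float:
    """Solvation energy of one atom in kcal/mol.

    ``asp`` is in cal/mol/A^2; the buried area ``sasa_ref - sasa_fold`` must
    come from non-negative areas. Negative output = stabilizing burial for a
    positive-ASP (apolar) atom.
    """
    if sasa_ref < 0 or sasa_fold < 0:
        raise ValueError("SASA values must be >= 0")
    return asp * (sasa_fold - sasa_ref) / 1000.0


@dataclass
class SolvationEnergyMap:
    """Per-atom energies plus residue and chain aggregations (kcal/mol)."""

    atom_table: pd.DataFrame     # chain_id, res_id, res_name, atom_name, energy
    residue_table: pd.DataFrame  # chain_id, res_id, res_name, atom_sum, entropy, energy
    chain_totals: pd.DataFrame   # chain_id, energy
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.chain_totals["energy"].sum())

    @property
    def per_chain(self) -> float:
        """Mean chain total — the headline kcal/mol/chain figure."""
        return float(self.chain_totals["energy"].mean())

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}: {v}\n")
            self.atom_table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SolvationEnergyMap":
        path = Path(path)
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("# ") and ":" in ln:
                k, _, v = ln[2:].partition(":")
                meta[k.strip()] = v.strip()
            else:
                body.append(ln)
        from io import StringIO

        atom_table = pd.read_csv(StringIO("".join(body)), sep="\t")
        res_tab, chain_tab = _aggregate(atom_table, entropy=None)
        return cls(atom_table=atom_table, residue_table=res_tab,
                   chain_totals=chain_tab, metadata=meta)


def _aggregate(atom_table: pd.DataFrame, entropy: EntropyTable | None):
    grp = atom_table.groupby(["chain_id", "res_id", "res_name"], sort=True)
    res_tab = grp["energy"].sum().reset_index().rename(columns={"energy": "atom_sum"})
    if entropy is not None:
        res_tab["entropy"] = [entropy.penalty(r) for r in res_tab["res_name"]]
    elif "entropy" in atom_table.attrs:
        res_tab["entropy"] = atom_table.attrs["entropy"]
    else:
        res_tab["entropy"] = 0.0
    res_tab["energy"] = res_tab["atom_sum"] + res_tab["entropy"]
    chain_tab = (
        res_tab.groupby("chain_id")["energy"].sum().reset_index()
    )
    return res_tab, chain_tab


def central_chains(structure: FibrilStructure) -> list[str]:
    """One protein chain per protofilament at the median axial position."""
    ax = structure.axis
    if ax is None:
        raise ContextError("structure has no axis; run assign_layers first")
    prot = structure.select(structure.protein_mask())
    pf_values = np.unique(prot.atoms.protofilament)
    pf_values = [p for p in pf_values if p] or [""]
    chosen = []
    for pf in pf_values:
        if pf:
            mask = prot.atoms.protofilament == pf
            sub = prot.select(mask)
        else:
            sub = prot
        cents = sub.chain_centroids()
        names = list(cents)
        t = np.array([cents[c] @ ax for c in names])
        order = np.argsort(t)
        chosen.append(names[order[len(order) // 2]])
    return chosen


def stability_map(
    structure: FibrilStructure,
    asp: ASPTable | None = None,
    entropy: EntropyTable | None = None,
    chains: list[str] | None = None,
    reference_mode: str = "extended-rebuild",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_entropy: bool = True,
    protonated_his: bool = False,
) -> SolvationEnergyMap:
    """Score the central chain(s) of a fibril in the full-fibril context.

    The folded-state SASA of every atom is computed with all chains (and any
    ligands) present; the reference-state SASA comes from the isolated
    (optionally extended-rebuilt) chain. Requires at least 3 assigned layers
    so the scored chain has both axial neighbors.
    """
    asp = asp or ASPTable.load()
    entropy = entropy or EntropyTable.load()
    if not include_entropy:
        entropy = EntropyTable(values={}, table_id="off")
    layers = np.unique(structure.atoms.layer)
    layers = layers[layers >= 0]
    if len(layers) < 3:
        raise ContextError(
            f"need >= 3 assigned layers for a central strand, have {len(layers)}"
        )
    if chains is None:
        chains = central_chains(structure)

    fold = compute_sasa(structure, probe=probe, n_points=n_points)

    rows = []
    fallbacks = []
    for cid in chains:
        cmask = structure.chain_mask(cid) & structure.protein_mask() & structure.heavy_mask()
        chain_struct = structure.select(structure.chain_mask(cid))
        ref = reference_sasa(
            chain_struct, mode=reference_mode, probe=probe, n_points=n_points
        )
        fallbacks.extend(ref.fallback_residues)
        # align: reference result covers the protein heavy atoms of the chain
        prot = chain_struct.select(chain_struct.protein_mask())
        ref_heavy = ref.area[prot.heavy_mask()]
        fold_heavy = fold.area[cmask]
        a = structure.atoms
        idx = np.where(cmask)[0]
        if len(idx) != len(ref_heavy):
            raise PairingError(
                f"chain {cid}: folded/reference atom counts differ "
                f"({len(idx)} vs {len(ref_heavy)})"
            )
        for k, i in enumerate(idx):
            cls = classify_atom(
                a.res_name[i], a.atom_name[i], a.element[i], protonated_his
            )
            if cls is None:
                continue
            e = atom_energy(ref_heavy[k], fold_heavy[k], asp[cls])
            rows.append(
                (str(a.chain_id[i]), int(a.res_id[i]), str(a.res_name[i]),
                 str(a.atom_name[i]), cls, e)
            )

    atom_table = pd.DataFrame(
        rows, columns=["chain_id", "res_id", "res_name", "atom_name", "class", "energy"]
    )
    res_tab, chain_tab = _aggregate(atom_table, entropy)
    meta = {
        "asp_table": asp.table_id,
        "entropy_table": entropy.table_id,
        "probe_radius": probe,
        "n_points": n_points,
        "reference_mode": reference_mode,
        "sign_convention": SIGN_CONVENTION,
        "scored_chains": ",".join(chains),
        "rebuild_fallback_residues": len(fallbacks),
    }
    return SolvationEnergyMap(atom_table, res_tab, chain_tab, metadata=meta)


def difference_map(
    a: SolvationEnergyMap, b: SolvationEnergyMap, max_unpaired_frac: float = 0.05
) -> SolvationEnergyMap:
    """Atom-wise ``a - b`` of two energy maps.

    Atoms are paired by (chain rank, residue number, residue name, atom
    name), where chain rank is the order of scored chains — so maps from two
    structures with different chain ids still pair. Unpaired atoms are
    excluded and counted; more than ``max_unpaired_frac`` unpaired raises
    :class:`PairingError` (the structures likely differ in construct).
    """
    ta = _ranked(a.atom_table)
    tb = _ranked(b.atom_table)
    key = ["chain_rank", "res_id", "res_name", "atom_name"]
    merged = ta.merge(tb, on=key, how="outer", suffixes=("_a", "_b"), indicator=True)
    unpaired = int((merged["_merge"] != "both").sum())
    n_total = len(merged)
    if n_total and unpaired / n_total > max_unpaired_frac:
        raise PairingError(
            f"{unpaired}/{n_total} atoms unpaired "
            f"(> {max_unpaired_frac:.0%}): different constructs?"
        )
    paired = merged[merged["_merge"] == "both"].copy()
    atom_table = pd.DataFrame(
        {
            "chain_id": paired["chain_id_a"],
            "res_id": paired["res_id"],
            "res_name": paired["res_name"],
            "atom_name": paired["atom_name"],
            "class": paired["class_a"],
            "energy": paired["energy_a"] - paired["energy_b"],
        }
    )
    res_tab, chain_tab = _aggregate(atom_table, entropy=None)
    meta = {
        "kind": "difference",
        "minuend": a.metadata.get("scored_chains", "?"),
        "subtrahend": b.metadata.get("scored_chains", "?"),
        "unpaired_atoms": unpaired,
        "sign_convention": SIGN_CONVENTION + "; positive = destabilized in a",
    }
    return SolvationEnergyMap(atom_table, res_tab, chain_tab, metadata=meta)


def _ranked(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    order = {c: i for i, c in enumerate(dict.fromkeys(t["chain_id"]))}
    t["chain_rank"] = [order[c] for c in t["chain_id"]]
    return t


def write_stability_structure(
    structure: FibrilStructure, emap: SolvationEnergyMap, path: str | Path
) -> None:
    """Write coordinates with per-atom energies in the B-factor column.

    Atoms not covered by the map get 0.00. Useful for coloring residues by
    stability in standard viewers.
    """
    out = structure.copy()
    n = len(out)
    b = np.zeros(n)
    lookup = {
        (r.chain_id, r.res_id, r.atom_name): r.energy
        for r in emap.atom_table.itertuples()
    }
    a = out.atoms
    for i in range(n):
        b[i] = lookup.get((str(a.chain_id[i]), int(a.res_id[i]), str(a.atom_name[i])), 0.0)
    out.atoms.set_annotation("b_factor", b)
    write_structure(out, path)
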