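"""Ligand-site geometry: buried area, hydrogen bonds, stacking, pose ranking.

Buried surface area follows the usual SASA-difference definition: the area a
partner loses on complex formation. Hydrogen bonds are detected on heavy
atoms (N/O donors with implied hydrogens, N/O acceptors) with a distance
cutoff, applying the D-H...A angle criterion only when explicit hydrogens
exist. Stacking metrics describe a column of planar ligands along the fibril
axis: centroid separations, plane tilts, and the solvent-face vs fibril-face
ring separations whose asymmetry is the curvature signature of a compressed
stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import params
from .errors import (
    ComparabilityError,
    InsufficientColumnError,
    SelectionError,
)
from .density import DensityGrid, VoxelMask, real_space_cc
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, compute_sasa, sphere_points
from .structure import FibrilStructure, estimate_axis


# -- buried surface area ----------------------------------------------------


def buried_area(
    complex_structure: FibrilStructure,
    ligand_selection: np.ndarray,
    side: str = "receptor",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """SASA (Angstrom^2) lost by one side upon complex formation.

    ``receptor``: SASA(receptor alone) - SASA(receptor in complex), where the
    receptor is everything except the selected ligand atoms (including any
    other ligand copies). ``ligand``: the analogous ligand-side loss.
    ``average``: the exact mean of both.
    """
    ligand_selection = np.asarray(ligand_selection, dtype=bool)
    if not ligand_selection.any():
        raise SelectionError("ligand selection is empty")
    if ligand_selection.all():
        raise SelectionError("ligand selection covers every atom: no receptor")
    if side not in {"receptor", "ligand", "average"}:
        raise ValueError(f"unknown side {side!r}")

    both = compute_sasa(complex_structure, probe=probe, n_points=n_points)

    def _side(sel: np.ndarray) -> float:
        alone = compute_sasa(
            complex_structure.select(sel), probe=probe, n_points=n_points
        )
        return alone.total - float(both.area[sel].sum())

    if side == "receptor":
        return _side(~ligand_selection)
    if side == "ligand":
        return _side(ligand_selection)
    return 0.5 * (_side(~ligand_selection) + _side(ligand_selection))


# -- hydrogen bonds ---------------------------------------------------------


@dataclass(frozen=True)
class HBond:
    donor_index: int
    acceptor_index: int
    distance: float
    angle: float | None
    donor_label: str
    acceptor_label: str

    @property
    def partner_residues(self) -> tuple[str, str]:
        return (self.donor_label.rsplit("/", 1)[0], self.acceptor_label.rsplit("/", 1)[0])


def _label(structure: FibrilStructure, i: int) -> str:
    a = structure.atoms
    return f"{a.chain_id[i]}:{a.res_name[i]}{a.res_id[i]}/{a.atom_name[i]}"


def _attached_hydrogens(structure: FibrilStructure, i: int) -> np.ndarray:
    """Coordinates of hydrogens covalently attached to heavy atom ``i``."""
    a = structure.atoms
    same_res = (
        (a.chain_id == a.chain_id[i])
        & (a.res_id == a.res_id[i])
        & (np.char.upper(a.element.astype("U2")) == "H")
    )
    idx = np.where(same_res)[0]
    if len(idx) == 0:
        return np.empty((0, 3))
    d = np.linalg.norm(structure.coord[idx] - structure.coord[i], axis=1)
    return structure.coord[idx[d < 1.25]]


def find_hbonds(
    structure: FibrilStructure,
    sel1: np.ndarray,
    sel2: np.ndarray,
    dist_cut: float = 3.5,
    ang_cut: float = 120.0,
) -> list[HBond]:
    """Hydrogen bonds between two disjoint selections.

    All N/O heavy-atom pairs across the selections in different residues
    within ``dist_cut`` qualify; when the putative donor carries explicit
    hydrogens, the best D-H...A angle must reach ``ang_cut`` degrees. In
    heavy-atom-only models both pairing directions are accepted on distance,
    and the donor is reported as the nitrogen of an N/O pair (first selection
    on ties) — roles are re-evaluated, so the list is symmetric under
    swapping the selections.
    """
    sel1 = np.asarray(sel1, dtype=bool)
    sel2 = np.asarray(sel2, dtype=bool)
    if np.any(sel1 & sel2):
        raise SelectionError("hydrogen-bond selections must be disjoint")
    a = structure.atoms
    el = np.char.upper(a.element.astype("U2"))
    polar = (el == "N") | (el == "O")
    idx1 = np.where(sel1 & polar)[0]
    idx2 = np.where(sel2 & polar)[0]
    if len(idx1) == 0 or len(idx2) == 0:
        return []
    tree = cKDTree(structure.coord[idx2])
    bonds: list[HBond] = []
    for i in idx1:
        for j2 in tree.query_ball_point(structure.coord[i], dist_cut):
            j = idx2[j2]
            if a.chain_id[i] == a.chain_id[j] and a.res_id[i] == a.res_id[j]:
                continue
            d = float(np.linalg.norm(structure.coord[i] - structure.coord[j]))
            donor, acceptor = _assign_roles(structure, i, j)
            h = _attached_hydrogens(structure, donor)
            angle: float | None = None
            if len(h):
                angle = _best_dha_angle(
                    structure.coord[donor], h, structure.coord[acceptor]
                )
                if angle < ang_cut:
                    continue
            bonds.append(
                HBond(
                    donor_index=int(donor),
                    acceptor_index=int(acceptor),
                    distance=d,
                    angle=angle,
                    donor_label=_label(structure, donor),
                    acceptor_label=_label(structure, acceptor),
                )
            )
    return bonds


def _assign_roles(structure: FibrilStructure, i: int, j: int) -> tuple[int, int]:
    """Donor/acceptor assignment: explicit H wins, else N over O, else i."""
    hi = len(_attached_hydrogens(structure, i))
    hj = len(_attached_hydrogens(structure, j))
    if hi and not hj:
        return i, j
    if hj and not hi:
        return j, i
    el = np.char.upper(structure.atoms.element.astype("U2"))
    if el[i] != el[j]:
        return (i, j) if el[i] == "N" else (j, i)
    return i, j


def _best_dha_angle(d: np.ndarray, hs: np.ndarray, acc: np.ndarray) -> float:
    best = 0.0
    for h in hs:
        v1 = d - h
        v2 = acc - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    return best


# -- ligand stacking --------------------------------------------------------


@dataclass
class StackProfile:
    """Geometry of a column of stacked planar ligands."""

    pair_table: pd.DataFrame  # per adjacent pair: separation, tilt, ring seps
    ring_labels: list[str]
    solvent_ring: str
    fibril_ring: str

    @property
    def mean_separation(self) -> float:
        return float(self.pair_table["separation"].mean())

    @property
    def mean_tilt(self) -> float:
        return float(self.pair_table["tilt"].mean())

    @property
    def mean_solvent_face(self) -> float:
        return float(self.pair_table[f"sep_{self.solvent_ring}"].mean())

    @property
    def mean_fibril_face(self) -> float:
        return float(self.pair_table[f"sep_{self.fibril_ring}"].mean())


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[2]


def stacking_metrics(
    structure: FibrilStructure,
    ring_table: dict | None = None,
    axis: np.ndarray | None = None,
    axis_point: np.ndarray | None = None,
) -> StackProfile:
    """Per-adjacent-pair stacking geometry of the ligand column.

    Ligand copies are ordered along the fibril axis. For each adjacent pair
    the whole-ligand centroid separation, the tilt between least-squares
    molecular planes (0-90 deg), and the centroid separation of each named
    ring are reported. Rings are classified by mean radial distance from the
    axis: the outermost is the solvent-facing ring, the innermost the
    fibril-facing ring.
    """
    ring_table = ring_table or params.load_ring_table()
    a = structure.atoms
    lig_mask = a.is_ligand
    if not lig_mask.any():
        raise InsufficientColumnError("structure contains no ligand atoms")
    ax = axis if axis is not None else (
        structure.axis if structure.axis is not None else estimate_axis(structure)
    )
    ax = np.asarray(ax, dtype=float)
    ax = ax / np.linalg.norm(ax)

    # one "copy" = one ligand residue
    keys: list[tuple[str, int, str]] = []
    seen = set()
    for i in np.where(lig_mask)[0]:
        key = (str(a.chain_id[i]), int(a.res_id[i]), str(a.res_name[i]))
        if key not in seen:
            seen.add(key)
            keys.append(key)
    if len(keys) < 2:
        raise InsufficientColumnError(
            f"need >= 2 ligand copies for stacking metrics, have {len(keys)}"
        )

    copies = []
    for c, r, name in keys:
        m = lig_mask & (a.chain_id == c) & (a.res_id == r)
        coords = structure.coord[m]
        names = a.atom_name[m]
        copies.append({"coords": coords, "names": list(names), "res_name": name})
    copies.sort(key=lambda cp: float(cp["coords"].mean(axis=0) @ ax))

    rings = ring_table.get(copies[0]["res_name"])
    if not rings:
        raise SelectionError(
            f"no ring definition for ligand {copies[0]['res_name']!r}"
        )
    ring_labels = list(rings)

    def ring_centroid(cp, label) -> np.ndarray:
        idx = [cp["names"].index(n) for n in rings[label] if n in cp["names"]]
        if not idx:
            raise SelectionError(f"ring {label} atoms missing from ligand copy")
        return cp["coords"][idx].mean(axis=0)

    # radial distances are measured from the fibril axis line; anchor it at
    # the receptor centroid when the structure has one, else at the ligands
    if axis_point is not None:
        center = np.asarray(axis_point, dtype=float)
    elif (~lig_mask).any():
        center = structure.coord[~lig_mask].mean(axis=0)
    else:
        center = np.vstack([cp["coords"] for cp in copies]).mean(axis=0)

    def radial(p: np.ndarray) -> float:
        v = p - center
        return float(np.linalg.norm(v - (v @ ax) * ax))

    mean_radial = {
        lab: float(np.mean([radial(ring_centroid(cp, lab)) for cp in copies]))
        for lab in ring_labels
    }
    solvent_ring = max(mean_radial, key=mean_radial.get)
    fibril_ring = min(mean_radial, key=mean_radial.get)

    rows = []
    for lower, upper in zip(copies[:-1], copies[1:]):
        sep = float(np.linalg.norm(upper["coords"].mean(axis=0) - lower["coords"].mean(axis=0)))
        n1 = _plane_normal(lower["coords"])
        n2 = _plane_normal(upper["coords"])
        cosang = abs(float(np.dot(n1, n2)))
        tilt = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
        row = {"separation": sep, "tilt": tilt}
        for lab in ring_labels:
            row[f"sep_{lab}"] = float(
                np.linalg.norm(ring_centroid(upper, lab) - ring_centroid(lower, lab))
            )
        rows.append(row)
    return StackProfile(
        pair_table=pd.DataFrame(rows),
        ring_labels=ring_labels,
        solvent_ring=solvent_ring,
        fibril_ring=fibril_ring,
    )


# -- pose comparison --------------------------------------------------------


def clash_count(
    structure: FibrilStructure, ligand_selection: np.ndarray, factor: float = 0.6
) -> int:
    """Heavy-atom ligand/receptor pairs closer than ``factor`` x radius sum."""
    sel = np.asarray(ligand_selection, dtype=bool)
    heavy = structure.heavy_mask()
    lig = structure.coord[sel & heavy]
    lig_r = structure.atoms.vdw_radius[sel & heavy]
    rec = structure.coord[~sel & heavy]
    rec_r = structure.atoms.vdw_radius[~sel & heavy]
    if len(lig) == 0 or len(rec) == 0:
        return 0
    tree = cKDTree(rec)
    count = 0
    max_cut = factor * (lig_r.max() + rec_r.max())
    for p, r in zip(lig, lig_r):
        for j in tree.query_ball_point(p, max_cut):
            if np.linalg.norm(p - rec[j]) < factor * (r + rec_r[j]):
                count += 1
    return count


def complementarity_score(
    structure: FibrilStructure,
    ligand_selection: np.ndarray,
    band: float = 1.0,
    n_points: int = 240,
) -> float:
    """Simplified (non-canonical) shape complementarity in [0, 1].

    Fraction of points on the ligand's van der Waals surface whose gap to the
    nearest receptor atom surface lies within ``[0, band]`` Angstrom. This is
    a documented stand-in for a full surface-normal complementarity
    statistic, adequate for ranking poses of one ligand in one site.
    """
    sel = np.asarray(ligand_selection, dtype=bool)
    heavy = structure.heavy_mask()
    lig_idx = np.where(sel & heavy)[0]
    rec_idx = np.where(~sel & heavy)[0]
    if len(lig_idx) == 0 or len(rec_idx) == 0:
        raise SelectionError("need both ligand and receptor atoms")
    pts = sphere_points(n_points)
    rec = structure.coord[rec_idx]
    rec_r = structure.atoms.vdw_radius[rec_idx]
    tree = cKDTree(rec)
    lig = structure.coord[lig_idx]
    lig_r = structure.atoms.vdw_radius[lig_idx]
    n_ok = 0
    n_all = 0
    for p, r in zip(lig, lig_r):
        surf = p + r * pts
        # drop points buried inside the ligand itself
        d_self = np.min(
            np.linalg.norm(surf[:, None, :] - lig[None, :, :], axis=2)
            / lig_r[None, :],
            axis=1,
        )
        exposed = surf[d_self >= 0.999]
        if len(exposed) == 0:
            continue
        d_near, j_near = tree.query(exposed, k=1)
        gap = d_near - rec_r[j_near]
        n_ok += int(np.sum((gap >= 0.0) & (gap <= band)))
        n_all += len(exposed)
    return n_ok / n_all if n_all else 0.0


RANK_RULE = "cc desc, clashes asc, hbonds desc, buried_area desc, complementarity desc"


def pose_report(
    poses: list[FibrilStructure],
    ligand_name: str = "LIG",
    grid: DensityGrid | None = None,
    site_mask: VoxelMask | None = None,
    sim_resolution: float = 3.8,
    hbond_dist: float = 3.5,
    hbond_angle: float = 120.0,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    receptor_tol: float = 1e-4,
) -> pd.DataFrame:
    """Score and rank candidate ligand poses sharing one receptor.

    Per pose: masked real-space correlation (when a map is given), buried
    area on the receptor side, hydrogen-bond count, clash count and the
    simplified complementarity score. Ranking is lexicographic under
    :data:`RANK_RULE`, recorded in the output's ``attrs``.
    """
    if len(poses) < 2:
        raise ComparabilityError("need at least two poses to rank")
    ref_rec = None
    rows = []
    for n, pose in enumerate(poses):
        lig_sel = pose.atoms.res_name == ligand_name
        if not lig_sel.any():
            raise SelectionError(f"pose {n}: no ligand residue {ligand_name!r}")
        rec_coords = pose.coord[~lig_sel]
        if ref_rec is None:
            ref_rec = rec_coords
        elif rec_coords.shape != ref_rec.shape or not np.allclose(
            rec_coords, ref_rec, atol=receptor_tol
        ):
            raise ComparabilityError(f"pose {n} has a different receptor")
        row = {"pose": n}
        if grid is not None and site_mask is not None:
            row["cc"] = real_space_cc(
                pose.select(lig_sel), grid, site_mask, sim_resolution=sim_resolution
            )
        row["buried_area"] = buried_area(
            pose, lig_sel, side="receptor", probe=probe, n_points=n_points
        )
        row["hbonds"] = len(
            find_hbonds(pose, lig_sel, ~lig_sel, dist_cut=hbond_dist, ang_cut=hbond_angle)
        )
        row["clashes"] = clash_count(pose, lig_sel)
        row["complementarity"] = complementarity_score(pose, lig_sel)
        rows.append(row)
    df = pd.DataFrame(rows)
    sort_cols, ascending = [], []
    if "cc" in df.columns:
        sort_cols.append("cc")
        ascending.append(False)
    sort_cols += ["clashes", "hbonds", "buried_area", "complementarity"]
    ascending += [True, False, False, False]
    df = df.sort_values(sort_cols, ascending=ascending, kind="mergesort").reset_index(
        drop=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["rank_rule"] = RANK_RULE
    return df
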