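"""Shrake-Rupley solvent-accessible surface area.

Quasi-uniform points are placed on each atom's solvent-expanded sphere
(radius ``r_vdw + probe``) with a deterministic generalized-spiral
construction, so results are bit-reproducible: no random rotations. The
accessible area of an atom is the fraction of its points outside every
neighbor's expanded sphere, times the sphere area.

Hydrogens are ignored (heavy-atom SASA): deposited fibril models are
heavy-atom and the solvation parameter tables are heavy-atom-typed.

The reference state for solvation energies is the isolated extended strand:
``reference_sasa`` either takes the chain as posed (``isolated-chain``) or
re-poses it residue-by-residue onto an ideal extended backbone
(``extended-rebuild``, phi = -120 deg, psi = +120 deg, omega = 180 deg)
before computing its SASA in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import MissingRadiusError
from .geometry import extended_backbone, kabsch_transform
from .structure import FibrilStructure

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    """Per-atom accessible areas (Angstrom^2), aligned to the input atoms."""

    area: np.ndarray
    probe_radius: float
    n_points: int
    #: residues for which an extended rebuild was impossible and the as-posed
    #: coordinates were used instead (chain_id, res_id)
    fallback_residues: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.area.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) points on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _heavy_subset(structure: FibrilStructure):
    mask = structure.heavy_mask()
    coords = structure.coord[mask]
    radii = structure.atoms.vdw_radius[mask]
    return mask, coords, radii


def compute_sasa(
    structure: FibrilStructure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake-Rupley SASA of every heavy atom in ``structure``.

    Returns one area per input atom (hydrogens get 0). Raises
    :class:`MissingRadiusError` if any heavy atom lacks a radius.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a meaningful area")
    mask, coords, radii = _heavy_subset(structure)
    if np.any(np.isnan(radii)):
        bad = np.where(np.isnan(radii))[0][0]
        names = structure.atoms.atom_name[mask]
        elems = structure.atoms.element[mask]
        raise MissingRadiusError(
            f"atom {names[bad]!r} (element {elems[bad]!r}) has no vdW radius"
        )
    areas = np.zeros(structure.atoms.array_length())
    if len(coords):
        areas[mask] = _shrake_rupley(coords, radii, probe, n_points)
    return SasaResult(area=areas, probe_radius=probe, n_points=n_points)


def _shrake_rupley(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int
) -> np.ndarray:
    expanded = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    out = np.empty(len(coords))
    for i in range(len(coords)):
        r_i = expanded[i]
        neighbors = tree.query_ball_point(coords[i], r_i + max_r)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            keep = d < r_i + expanded[nb]
            nb = nb[keep]
        else:
            nb = np.empty(0, dtype=int)
        if len(nb) == 0:
            frac = 1.0
        else:
            surf = coords[i] + r_i * pts
            diff = surf[:, None, :] - coords[nb][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            accessible = np.all(d2 > expanded[nb] ** 2, axis=1)
            frac = accessible.mean()
        out[i] = frac * 4.0 * np.pi * r_i**2
    return out


# -- reference state --------------------------------------------------------


def rebuild_extended(chain: FibrilStructure) -> tuple[FibrilStructure, list[tuple[str, int]]]:
    """Re-pose a single chain onto an ideal extended backbone.

    Each residue is moved rigidly: the least-squares transform taking its
    (N, CA, C) atoms onto the ideal-dihedral backbone trace is applied to all
    of its atoms, preserving residue identity, atom composition and internal
    side-chain geometry. Residues missing any of N/CA/C are left as posed and
    reported as fallbacks.
    """
    out = chain.copy()
    atoms = out.atoms
    res_keys: list[tuple[str, int]] = []
    seen = set()
    for c, r in zip(atoms.chain_id, atoms.res_id):
        key = (str(c), int(r))
        if key not in seen:
            seen.add(key)
            res_keys.append(key)
    ideal = extended_backbone(len(res_keys))
    fallbacks: list[tuple[str, int]] = []
    coords = atoms.coord.copy()
    for idx, (c, r) in enumerate(res_keys):
        rmask = (atoms.chain_id == c) & (atoms.res_id == r)
        names = atoms.atom_name[rmask]
        bb = {}
        for want in ("N", "CA", "C"):
            hit = np.where(names == want)[0]
            if len(hit):
                bb[want] = coords[rmask][hit[0]]
        if len(bb) < 3:
            fallbacks.append((c, r))
            continue
        mobile = np.array([bb["N"], bb["CA"], bb["C"]])
        R, t = kabsch_transform(mobile, ideal[idx])
        coords[rmask] = coords[rmask] @ R.T + t
    out.atoms.coord = coords
    return out, fallbacks


def reference_sasa(
    chain: FibrilStructure,
    mode: str = "extended-rebuild",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Reference-state SASA of an isolated polypeptide chain.

    ``extended-rebuild`` re-poses the chain with ideal extended backbone
    dihedrals before the area calculation; ``isolated-chain`` keeps the input
    conformation and simply drops every other chain. Ligand and water atoms
    are excluded in both modes.
    """
    if mode not in {"extended-rebuild", "isolated-chain"}:
        raise ValueError(f"unknown reference mode {mode!r}")
    prot = chain.select(chain.protein_mask())
    if len(prot.chain_ids) != 1:
        raise ValueError("reference_sasa expects a single polypeptide chain")
    fallbacks: list[tuple[str, int]] = []
    if mode == "extended-rebuild":
        prot, fallbacks = rebuild_extended(prot)
    result = compute_sasa(prot, probe=probe, n_points=n_points)
    result.fallback_residues = fallbacks
    return result
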