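"""Synthetic fibrils, ligand columns and density maps with known ground truth.

The generator emulates the geometry every analysis stage needs, with no
download: a two-protofilament fibril built by helical stacking of a template
layer (poly-Ala hairpin or poly-Gly strand, ~4.8 Angstrom rise, small twist),
a column of planar mock ligands in the inter-protofilament cleft (optionally
"curved" by compressing the solvent-facing ring spacing), and Gaussian-atom
density maps whose ligand amplitude fraction *is* the ground-truth occupancy.

Everything is a pure function of the :class:`FixtureSpec` (including its
seed): same spec, bit-identical output.

The template is deliberately not a realistic tau fold: residues are numbered
306..353 so that the segments the analyses care about (the 340-343 hinge,
the 345-352 reference backbone) exist, but the backbone path is a flat
hairpin, not the C-shape of the real protofilament.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc

from . import params
from .density import DensityGrid
from .geometry import extended_backbone, place_atom, rotation_about_axis
from .structure import (
    FibrilStructure,
    HelicalSymmetry,
    annotate,
    concat,
    expand_helical,
)

FIRST_RESIDUE = 306

#: typical cross-beta helical parameters; the twist is a fixture convention
#: (deposited paired helical filaments twist by about a degree per layer),
#: not a measured value.
DEFAULT_RISE = 4.8
DEFAULT_TWIST = -1.2


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic world."""

    n_layers: int = 5
    rise: float = DEFAULT_RISE
    twist: float = DEFAULT_TWIST
    protofilaments: int = 2
    template: str = "poly-ala-hairpin"  # or "poly-gly-strand"
    residues_per_strand: int = 24
    # ligand column
    ligand_count: int | None = None  # None -> one per layer
    ligand_spacing: float = DEFAULT_RISE
    solvent_edge_compression: float = 0.0  # 0 = straight column; else target A
    # density map
    voxel_size: float = 1.0
    resolution: float = 3.8
    ligand_amplitude: float = 1.0  # ground-truth occupancy fraction
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.protofilaments not in (1, 2):
            raise ValueError("n_layers >= 1 and protofilaments in {1, 2} required")
        if self.rise <= 0 or self.ligand_spacing <= 0 or self.voxel_size <= 0:
            raise ValueError("lengths must be > 0")
        if not (0.0 <= self.ligand_amplitude <= 1.5):
            raise ValueError("ligand amplitude fraction must lie in [0, 1.5]")
        if self.residues_per_strand < 2:
            raise ValueError("need at least 2 residues per strand")

    def with_(self, **kwargs) -> "FixtureSpec":
        return replace(self, **kwargs)


# -- template layer ---------------------------------------------------------

_BOND_C_O = 1.231
_ANGLE_CA_C_O = 120.5
_BOND_CA_CB = 1.530
_ANGLE_N_CA_CB = 110.5


def _strand_atoms(n_res: int, res_name: str, first_res: int):
    """Extended strand with N/CA/C/O (+CB for Ala), principal axes aligned.

    Returns (names, elements, res_ids, res_names, coords) with the strand
    direction along +y and the backbone pleat in the x/y plane, so a layer
    stays thin along the eventual fibril axis (z).
    """
    bb = extended_backbone(n_res)
    names, elements, res_ids, res_names, coords = [], [], [], [], []
    for i in range(n_res):
        n_i, ca_i, c_i = bb[i]
        res_atoms = [("N", "N", n_i), ("CA", "C", ca_i), ("C", "C", c_i)]
        # carbonyl O in the peptide plane, anti to the next N
        if i + 1 < n_res:
            o_i = place_atom(bb[i + 1][0], ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O, 180.0)
        else:
            o_i = place_atom(n_i, ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O, 0.0)
        res_atoms.append(("O", "O", o_i))
        if res_name == "ALA":
            cb = place_atom(c_i, n_i, ca_i, _BOND_CA_CB, _ANGLE_N_CA_CB, 122.6)
            res_atoms.append(("CB", "C", cb))
        for nm, el, pos in res_atoms:
            names.append(nm)
            elements.append(el)
            res_ids.append(first_res + i)
            res_names.append(res_name)
            coords.append(pos)
    coords = np.array(coords)
    # principal-axis alignment: strand axis -> y, pleat -> x, thin axis -> z
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    R = np.array([vt[1], vt[0], vt[2]])  # rows: new x, y, z in old frame
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    coords = centered @ R.T
    return names, elements, res_ids, res_names, coords


def _build_atom_array(records) -> struc.AtomArray:
    n = len(records["names"])
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(records["coords"], dtype=np.float32)
    arr.atom_name = np.array(records["names"], dtype="U6")
    arr.element = np.array(records["elements"], dtype="U2")
    arr.res_id = np.array(records["res_ids"], dtype=int)
    arr.res_name = np.array(records["res_names"], dtype="U5")
    arr.chain_id = np.array(records["chains"], dtype="U4")
    arr.hetero = np.asarray(records["hetero"], dtype=bool)
    return arr


def make_template_layer(spec: FixtureSpec) -> FibrilStructure:
    """One fibril rung: hairpin (or single strand) per protofilament.

    Protofilament A sits at x > 0, protofilament B is its C2 image about the
    fibril (z) axis; the inter-protofilament cleft straddles x ~ 0. Residues
    are numbered from 306.
    """
    res_name = "ALA" if spec.template == "poly-ala-hairpin" else "GLY"
    if spec.template not in {"poly-ala-hairpin", "poly-gly-strand"}:
        raise ValueError(f"unknown template {spec.template!r}")
    n = spec.residues_per_strand
    rec = {k: [] for k in ("names", "elements", "res_ids", "res_names", "coords",
                           "chains", "hetero")}

    def add_strand(first_res: int, offset: np.ndarray, flip: bool, chain: str):
        names, els, rids, rnames, coords = _strand_atoms(n, res_name, first_res)
        if flip:
            R = rotation_about_axis([0, 0, 1], 180.0)
            coords = coords @ R.T
        coords = coords + offset
        rec["names"] += names
        rec["elements"] += els
        rec["res_ids"] += list(rids)
        rec["res_names"] += rnames
        rec["coords"] += list(coords)
        rec["chains"] += [chain] * len(names)
        rec["hetero"] += [False] * len(names)

    # protofilament A: strands at x = 7 and 16, running along y; the 14 A
    # cleft between the protofilaments keeps ligand density resolvable from
    # the walls at cryoEM-like resolution
    add_strand(FIRST_RESIDUE, np.array([7.0, 0.0, 0.0]), False, "A")
    if spec.template == "poly-ala-hairpin":
        add_strand(FIRST_RESIDUE + n, np.array([16.0, 0.0, 0.0]), True, "A")
    arr_a = _build_atom_array(rec)

    pieces = [arr_a]
    if spec.protofilaments == 2:
        arr_b = arr_a.copy()
        R = rotation_about_axis([0, 0, 1], 180.0)
        arr_b.coord = arr_b.coord @ np.asarray(R.T, dtype=np.float32)
        arr_b.chain_id = np.full(arr_b.array_length(), "B", dtype="U4")
        pieces.append(arr_b)
    arr = pieces[0]
    for p in pieces[1:]:
        arr = arr + p

    fib = annotate(arr)
    fib.axis = np.array([0.0, 0.0, 1.0])
    fib.atoms.set_annotation("layer", np.zeros(len(fib), dtype=int))
    pf = np.where(fib.atoms.chain_id == "A", "A", "B").astype("U1")
    fib.atoms.set_annotation("protofilament", pf)
    return fib


def make_fibril(spec: FixtureSpec) -> FibrilStructure:
    """Helically stacked two-protofilament fibril with ground-truth layers."""
    layer = make_template_layer(spec)
    sym = HelicalSymmetry(rise=spec.rise, twist=spec.twist)
    return expand_helical(layer, sym, spec.n_layers)


# -- mock ligand column -----------------------------------------------------

_RING_OFFSETS = {"RA": 0.0, "RC": 2.4, "RD": 4.8}
_RING_RADIUS = 1.40


def _mock_ligand(anchor_y: float) -> tuple[list[str], np.ndarray]:
    """Planar tri-ring scaffold in the z = 0 plane, rings along +y.

    RA is the innermost (fibril-facing) ring, RD the outermost
    (solvent-facing) one; hexagon vertices of carbon atoms, 1.4 Angstrom
    ring radius — geometry only, no chemistry.
    """
    names, coords = [], []
    for label, dy in _RING_OFFSETS.items():
        for v in range(6):
            t = np.pi / 3.0 * v + np.pi / 6.0
            names.append(f"{label[1]}{v + 1}")
            coords.append(
                [_RING_RADIUS * np.cos(t), anchor_y + dy + _RING_RADIUS * np.sin(t), 0.0]
            )
    return names, np.array(coords)


def make_ligand_column(
    fibril: FibrilStructure, spec: FixtureSpec, anchor_y: float = 8.0
) -> FibrilStructure:
    """Fibril plus a column of mock ligands in the inter-protofilament cleft.

    Ligand ``k`` sits at ``z = k * spacing`` (twisted with the helix) in the
    cleft at x ~ 0. A non-zero ``solvent_edge_compression`` shears each copy
    in proportion to its index so that adjacent solvent-facing (RD) ring
    centroids end up exactly that many Angstrom apart while the fibril-facing
    (RA) spacing widens: an idealized curved stack.
    """
    count = spec.ligand_count if spec.ligand_count is not None else spec.n_layers
    if count > spec.n_layers:
        raise ValueError(
            f"ligand count {count} exceeds n_layers {spec.n_layers}"
        )
    if count < 1:
        raise ValueError("ligand count must be >= 1")
    names, base = _mock_ligand(anchor_y)
    y_c = base[:, 1].mean()
    y_d = base[12:, 1].mean()  # RD ring centroid
    if spec.solvent_edge_compression > 0:
        shear = (spec.solvent_edge_compression - spec.ligand_spacing) / (y_d - y_c)
    else:
        shear = 0.0

    rec = {k: [] for k in ("names", "elements", "res_ids", "res_names", "coords",
                           "chains", "hetero")}
    for k in range(count):
        coords = base.copy()
        coords[:, 2] += (coords[:, 1] - y_c) * (k * shear)  # curvature shear
        coords[:, 2] += k * spec.ligand_spacing
        R = rotation_about_axis([0, 0, 1], k * spec.twist)
        coords = coords @ R.T
        rec["names"] += names
        rec["elements"] += ["C"] * len(names)
        rec["res_ids"] += [k + 1] * len(names)
        rec["res_names"] += ["LIG"] * len(names)
        rec["coords"] += list(coords)
        rec["chains"] += ["L"] * len(names)
        rec["hetero"] += [True] * len(names)
    lig_arr = _build_atom_array(rec)
    ligands = annotate(lig_arr)
    ligands.axis = fibril.axis
    ligands.atoms.set_annotation(
        "layer", np.repeat(np.arange(count), len(names)).astype(int)
    )
    return concat([fibril, ligands])


# -- density maps -----------------------------------------------------------


def simulate_map(
    structure: FibrilStructure,
    spec: FixtureSpec,
    padding: float = 14.0,
    ref_range: tuple[int, int] = (345, 352),
) -> DensityGrid:
    """Gaussian-atom map whose ligand amplitude encodes true occupancy.

    The ligand-only component is normalized so that at amplitude fraction 1.0
    its density peak equals the protein map's peak over the reference
    backbone (residues 345-352); the fraction therefore *is* the ground-truth
    occupancy that the three-mask estimator should recover. Optional
    independent Gaussian voxel noise is seeded from the spec.
    """
    from .density import simulate_density  # local to avoid cycle at import

    if spec.voxel_size >= spec.resolution / 2:
        raise ValueError(
            f"voxel {spec.voxel_size} A too coarse for resolution {spec.resolution} A"
        )
    lig_mask = structure.atoms.is_ligand
    prot = structure.select(~lig_mask)
    grid = simulate_density(
        prot, resolution=spec.resolution, voxel_size=spec.voxel_size, padding=padding
    )
    values = grid.values.astype(np.float64)

    if lig_mask.any() and spec.ligand_amplitude > 0:
        ligs = structure.select(lig_mask)
        lig_grid = simulate_density(ligs, grid=grid, resolution=spec.resolution)
        # peak calibration: reference backbone vs ligand region
        pts = grid.voxel_coords()
        a = prot.atoms
        ref_sel = (
            (a.res_id >= ref_range[0]) & (a.res_id <= ref_range[1])
            & np.isin(a.atom_name, ["N", "CA", "C", "O"])
        )
        if not ref_sel.any():
            raise ValueError(f"template lacks reference residues {ref_range}")
        from scipy.spatial import cKDTree

        d_ref, _ = cKDTree(prot.coord[ref_sel]).query(pts, k=1)
        d_lig, _ = cKDTree(ligs.coord).query(pts, k=1)
        p_ref = float(values.ravel()[d_ref <= 2.0].max())
        p_lig = float(lig_grid.values.ravel()[d_lig <= 2.0].max())
        values += spec.ligand_amplitude * (p_ref / p_lig) * lig_grid.values

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return DensityGrid(
        values=values.astype(np.float32),
        voxel_size=grid.voxel_size,
        origin=grid.origin.copy(),
    )


def make_hinged_fibril(
    spec: FixtureSpec,
    hinge_residues: tuple[int, int] = (340, 343),
    dz: float = 4.2,
    layer: int | None = None,
) -> FibrilStructure:
    """Fibril with one layer's hinge segment pushed along the axis.

    The C-alpha (and all other) atoms of ``hinge_residues`` in one layer
    (default: the top layer) are translated ``dz`` Angstrom along the axis,
    so the inter-layer spacing at those residues jumps from the rise to
    rise + dz — the generator ground truth for perturbation profiles.
    """
    fib = make_fibril(spec)
    target_layer = spec.n_layers - 1 if layer is None else layer
    a = fib.atoms
    mask = (
        (a.layer == target_layer)
        & (a.res_id >= hinge_residues[0])
        & (a.res_id <= hinge_residues[1])
    )
    if not mask.any():
        raise ValueError(f"no atoms in residues {hinge_residues}")
    ax = fib.axis if fib.axis is not None else np.array([0.0, 0.0, 1.0])
    coords = a.coord.copy()
    coords[mask] += (dz * ax).astype(coords.dtype)
    fib.atoms.coord = coords
    return fib


def ground_truth(spec: FixtureSpec) -> dict:
    """Manifest of the generator's known truths for a given spec."""
    count = spec.ligand_count if spec.ligand_count is not None else spec.n_layers
    return {
        "n_chains": spec.n_layers * spec.protofilaments,
        "rise": spec.rise,
        "twist": spec.twist,
        "ligand_count": count,
        "ligand_spacing": spec.ligand_spacing,
        "solvent_edge_compression": spec.solvent_edge_compression or None,
        "occupancy": spec.ligand_amplitude,
        "first_residue": FIRST_RESIDUE,
        "last_residue": FIRST_RESIDUE + 2 * spec.residues_per_strand - 1
        if spec.template == "poly-ala-hairpin"
        else FIRST_RESIDUE + spec.residues_per_strand - 1,
        "seed": spec.seed,
    }
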