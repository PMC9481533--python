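"""Small rigid-body and internal-coordinate helpers shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector cannot be normalized")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (degrees)."""
    a = unit(axis)
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    # Rodrigues form
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto ``target``.

    Returns the rotation matrix and translation such that
    ``mobile @ R.T + t`` approximates ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from A-B-C.

    D is at distance ``bond`` from C, with angle B-C-D equal to ``angle_deg``
    and dihedral A-B-C-D equal to ``dihedral_deg``.
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Ideal backbone geometry (Engh-Huber-like averages)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7


def extended_backbone(n_residues: int, phi: float = -120.0, psi: float = 120.0,
                      omega: float = 180.0) -> np.ndarray:
    """Ideal-geometry N/CA/C trace for an extended polypeptide.

    Returns an array of shape ``(n_residues, 3, 3)``: per residue the N, CA
    and C positions of a chain built with the given backbone dihedrals.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    coords = np.zeros((n_residues, 3, 3))
    # seed residue in a canonical pose
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    coords[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])                 # CA
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])                          # C
    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords[i] = [n_i, ca_i, c_i]
    return coords
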