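"""CryoEM density grids, voxel masks, occupancy and model-map correlation.

The ligand-occupancy estimate follows the three-mask recipe: a *site* mask
around the ligand density, a *reference* mask around a stretch of protein
backbone modeled at full occupancy, and a *solvent* mask well away from the
model. With ``max`` the maximum voxel value inside a mask and ``avg`` the
mean,

    occupancy = (max(site) - avg(solvent)) / (max(reference) - avg(solvent))

which is invariant to affine rescaling of the map. Values are not clamped:
an estimate slightly above 1 or below 0 is reported as-is together with the
three intermediate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import mrcfile
from scipy.spatial import cKDTree

from .errors import (
    DegenerateReferenceError,
    EmptyMaskError,
    MaskOverlapError,
    StructureParseError,
    UndefinedCorrelationError,
)
from .structure import FibrilStructure

#: approximate atomic numbers for Gaussian-atom amplitudes
_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
                  "CL": 17, "SE": 34, "BR": 35, "I": 53}


@dataclass
class DensityGrid:
    """Regular 3-D map in canonical x/y/z axis order.

    ``values[i, j, k]`` is the voxel at Cartesian position
    ``origin + (i, j, k) * voxel_size`` (Angstrom).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be > 0")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with >= 2 voxels per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_coords(self) -> np.ndarray:
        """(N, 3) Cartesian centers of all voxels, in x-fastest C order."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        return self.origin + idx * self.voxel_size


@dataclass
class VoxelMask:
    """Boolean grid congruent with a :class:`DensityGrid`."""

    mask: np.ndarray
    label: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyMaskError(f"{self.label} mask is empty")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 map, normalizing axis order to canonical x/y/z.

    The MRC2014 axis-correspondence fields (mapc/mapr/maps) are honored, so
    maps stored with permuted axes load to identical canonical values.
    Non-orthogonal cells are rejected (cryoEM maps are orthogonal).
    """
    try:
        with mrcfile.open(str(path), permissive=False) as mrc:
            header = mrc.header
            data = np.asarray(mrc.data)
            if data is None or data.ndim != 3:
                raise StructureParseError(f"{path}: not a 3-D map")
            angles = (float(header.cellb.alpha), float(header.cellb.beta),
                      float(header.cellb.gamma))
            if any(abs(a - 90.0) > 1e-3 for a in angles):
                raise StructureParseError(
                    f"{path}: non-orthogonal cell {angles} not supported"
                )
            # data axes are (sections, rows, columns) -> crystal axes
            # (maps, mapr, mapc); build values[x, y, z]
            axis_of = {int(header.mapc): 2, int(header.mapr): 1, int(header.maps): 0}
            # axis_of[crystal axis 1..3] = numpy axis in `data`
            perm = [axis_of[1], axis_of[2], axis_of[3]]
            values = np.transpose(data, axes=perm)
            cell = np.array([header.cella.x, header.cella.y, header.cella.z], float)
            dims = np.array(values.shape, dtype=float)
            voxels = cell / dims
            if np.any(voxels <= 0):
                raise StructureParseError(f"{path}: zero-sized cell/axis in header")
            if np.ptp(voxels) > 1e-3:
                raise StructureParseError(
                    f"{path}: anisotropic voxels {voxels} not supported"
                )
            nstart = np.array(
                [int(header.nxstart), int(header.nystart), int(header.nzstart)], float
            )
            origin = np.array(
                [float(header.origin.x), float(header.origin.y), float(header.origin.z)]
            )
            origin = origin + nstart * voxels
            return DensityGrid(values=values, voxel_size=float(voxels[0]), origin=origin)
    except (StructureParseError, EmptyMaskError):
        raise
    except Exception as exc:
        raise StructureParseError(f"could not read map {path}: {exc}") from exc


def write_map(grid: DensityGrid, path) -> None:
    """Write a canonical-order grid as an MRC2014 file."""
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0))))
        nx, ny, nz = grid.shape
        mrc.header.cella = (nx * grid.voxel_size, ny * grid.voxel_size,
                            nz * grid.voxel_size)
        mrc.header.origin = tuple(grid.origin)
        mrc.update_header_stats()


# -- masks ------------------------------------------------------------------


def build_masks(
    structure: FibrilStructure,
    grid: DensityGrid,
    site_selection: np.ndarray,
    ref_selection: np.ndarray,
    site_r: float = 2.0,
    ref_r: float = 2.0,
    solvent_near: float = 6.0,
    solvent_far: float = 12.0,
) -> tuple[VoxelMask, VoxelMask, VoxelMask]:
    """Site / reference / solvent masks from atom selections.

    Site voxels lie within ``site_r`` of any site-selection atom; reference
    voxels within ``ref_r`` of any backbone atom of the reference selection;
    solvent voxels between ``solvent_near`` and ``solvent_far`` of *any*
    model atom. The solvent shell is disjoint from the atom masks by
    construction; site/reference overlap (shared atoms or shared voxels)
    raises :class:`MaskOverlapError`.
    """
    site_selection = np.asarray(site_selection, dtype=bool)
    ref_selection = np.asarray(ref_selection, dtype=bool)
    if not site_selection.any() or not ref_selection.any():
        raise EmptyMaskError("site/reference atom selections must be non-empty")
    if np.any(site_selection & ref_selection):
        raise MaskOverlapError("site and reference selections share atoms")
    if not solvent_far > solvent_near > max(site_r, ref_r):
        raise ValueError("require solvent_far > solvent_near > max(site_r, ref_r)")

    pts = grid.voxel_coords()
    shape = grid.shape

    def _dist_to(coords: np.ndarray) -> np.ndarray:
        tree = cKDTree(coords)
        d, _ = tree.query(pts, k=1)
        return d.reshape(shape)

    d_site = _dist_to(structure.coord[site_selection])
    d_ref = _dist_to(structure.coord[ref_selection])
    d_all = _dist_to(structure.coord)

    site = d_site <= site_r
    ref = d_ref <= ref_r
    solvent = (d_all >= solvent_near) & (d_all <= solvent_far)
    if np.any(site & ref):
        raise MaskOverlapError("site and reference masks overlap voxel-wise")
    return (
        VoxelMask(site, "site"),
        VoxelMask(ref, "reference"),
        VoxelMask(solvent, "solvent"),
    )


def backbone_range_selection(
    structure: FibrilStructure, start: int, stop: int,
    atom_names=("N", "CA", "C", "O"),
) -> np.ndarray:
    """Boolean mask over backbone atoms of residues ``start..stop`` inclusive."""
    a = structure.atoms
    return (
        (a.res_id >= start)
        & (a.res_id <= stop)
        & np.isin(a.atom_name, list(atom_names))
        & structure.protein_mask()
    )


# -- occupancy --------------------------------------------------------------


@dataclass
class OccupancyResult:
    occupancy: float
    max_site: float
    max_reference: float
    mean_solvent: float
    trimmed: bool = False


def occupancy(
    grid: DensityGrid,
    site: VoxelMask,
    ref: VoxelMask,
    solvent: VoxelMask,
    trimmed_max: bool = False,
    trim_quantile: float = 0.99,
) -> OccupancyResult:
    """Three-mask ligand occupancy estimate (not clamped to [0, 1]).

    ``trimmed_max`` replaces the literal maximum with the given quantile of
    in-mask values for noise robustness; off by default (the literal reading
    of the formula).
    """
    v = grid.values

    def _max(m: VoxelMask) -> float:
        vals = v[m.mask]
        if trimmed_max:
            return float(np.quantile(vals, trim_quantile))
        return float(vals.max())

    max_site = _max(site)
    max_ref = _max(ref)
    mean_solv = float(v[solvent.mask].mean())
    if max_ref <= mean_solv:
        raise DegenerateReferenceError(
            f"max(reference)={max_ref:.4g} <= avg(solvent)={mean_solv:.4g}"
        )
    occ = (max_site - mean_solv) / (max_ref - mean_solv)
    return OccupancyResult(occ, max_site, max_ref, mean_solv, trimmed=trimmed_max)


# -- model-map density simulation and correlation ---------------------------


def simulate_density(
    structure: FibrilStructure,
    grid: DensityGrid | None = None,
    resolution: float = 3.8,
    voxel_size: float = 1.0,
    padding: float = 6.0,
    amplitudes: np.ndarray | None = None,
) -> DensityGrid:
    """Gaussian-atom density: one isotropic Gaussian per heavy atom.

    sigma = resolution / 3; amplitude proportional to atomic number unless
    per-atom ``amplitudes`` are given. If no ``grid`` is passed, a grid
    covering the model plus ``padding`` Angstrom is created.
    """
    heavy = structure.heavy_mask()
    coords = structure.coord[heavy]
    if amplitudes is None:
        amplitudes = np.array(
            [_ATOMIC_NUMBER.get(e, 6) for e in structure.atoms.element[heavy]],
            dtype=float,
        )
    else:
        amplitudes = np.asarray(amplitudes, dtype=float)[heavy]
    if grid is None:
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
        shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 2)
        grid = DensityGrid(
            values=np.zeros(shape, dtype=np.float32),
            voxel_size=voxel_size,
            origin=lo,
        )
    values = np.zeros(grid.shape, dtype=np.float64)
    sigma = resolution / 3.0
    cut = 4.0 * sigma
    vs = grid.voxel_size
    shape = np.array(grid.shape)
    axes = [grid.origin[d] + np.arange(grid.shape[d]) * vs for d in range(3)]
    for pos, amp in zip(coords, amplitudes):
        lo_idx = np.maximum(np.floor((pos - cut - grid.origin) / vs).astype(int), 0)
        hi_idx = np.minimum(np.ceil((pos + cut - grid.origin) / vs).astype(int) + 1, shape)
        if np.any(lo_idx >= hi_idx):
            continue
        gx = np.exp(-0.5 * ((axes[0][lo_idx[0]:hi_idx[0]] - pos[0]) / sigma) ** 2)
        gy = np.exp(-0.5 * ((axes[1][lo_idx[1]:hi_idx[1]] - pos[1]) / sigma) ** 2)
        gz = np.exp(-0.5 * ((axes[2][lo_idx[2]:hi_idx[2]] - pos[2]) / sigma) ** 2)
        values[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] += (
            amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return DensityGrid(values=values.astype(np.float32), voxel_size=vs,
                       origin=grid.origin.copy())


def real_space_cc(
    structure: FibrilStructure,
    grid: DensityGrid,
    mask: VoxelMask,
    sim_resolution: float = 3.8,
) -> float:
    """Masked Pearson correlation between the map and a simulated model map."""
    sim = simulate_density(structure, grid=grid, resolution=sim_resolution)
    obs = grid.values[mask.mask].astype(float)
    calc = sim.values[mask.mask].astype(float)
    if np.ptp(obs) == 0 or np.ptp(calc) == 0:
        raise UndefinedCorrelationError(
            "constant observed or simulated density inside the mask"
        )
    return float(np.corrcoef(obs, calc)[0, 1])
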