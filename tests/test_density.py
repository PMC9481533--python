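"""Density grids, masks, the three-mask occupancy estimate, model-map CC."""

import numpy as np
import mrcfile
import pytest

from fibrilstab import (
    DensityGrid,
    VoxelMask,
    build_masks,
    make_ligand_column,
    occupancy,
    read_map,
    real_space_cc,
    simulate_density,
    simulate_map,
    write_map,
)
from fibrilstab.density import backbone_range_selection
from fibrilstab.errors import (
    DegenerateReferenceError,
    EmptyMaskError,
    MaskOverlapError,
    StructureParseError,
    UndefinedCorrelationError,
)
from conftest import build_toy, single_atom


@pytest.fixture(scope="module")
def combo(small_spec, small_fibril):
    return make_ligand_column(small_fibril, small_spec)


@pytest.fixture(scope="module")
def combo_map(combo, small_spec):
    return simulate_map(combo, small_spec, ref_range=(306, 313))


@pytest.fixture(scope="module")
def masks(combo, combo_map):
    site_sel = combo.atoms.is_ligand
    ref_sel = backbone_range_selection(combo, 306, 313)
    return build_masks(combo, combo_map, site_sel, ref_sel)


class TestMapIO:
    def test_round_trip(self, combo_map, tmp_path):
        p = tmp_path / "map.mrc"
        write_map(combo_map, p)
        back = read_map(p)
        np.testing.assert_array_equal(back.values, combo_map.values)
        assert back.voxel_size == pytest.approx(combo_map.voxel_size)
        np.testing.assert_allclose(back.origin, combo_map.origin, atol=1e-4)

    def test_axis_permutation_canonicalized(self, tmp_path):
        """A map saved with permuted axis order loads to identical canonical
        values (the MRC axis-correspondence fields are honored)."""
        rng = np.random.default_rng(7)
        vals = rng.random((4, 5, 6)).astype(np.float32)  # canonical x,y,z
        ref = DensityGrid(values=vals, voxel_size=1.5)
        p0 = tmp_path / "canonical.mrc"
        write_map(ref, p0)
        # store with x as sections and z as columns: data[x, y, z],
        # so columns=z -> mapc=3, rows=y -> mapr=2, sections=x -> maps=1
        p1 = tmp_path / "permuted.mrc"
        with mrcfile.new(str(p1), overwrite=True) as mrc:
            mrc.set_data(np.ascontiguousarray(vals))
            mrc.header.mapc, mrc.header.mapr, mrc.header.maps = 3, 2, 1
            mrc.header.cella = (4 * 1.5, 5 * 1.5, 6 * 1.5)
            mrc.update_header_stats()
        a = read_map(p0)
        b = read_map(p1)
        np.testing.assert_array_equal(a.values, b.values)

    def test_corrupt_file_errors(self, tmp_path):
        p = tmp_path / "bad.mrc"
        p.write_bytes(b"not a map at all")
        with pytest.raises(StructureParseError):
            read_map(p)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            DensityGrid(values=np.zeros((1, 5, 5)), voxel_size=1.0)
        with pytest.raises(ValueError):
            DensityGrid(values=np.zeros((5, 5, 5)), voxel_size=-1.0)


class TestMasks:
    def test_discrete_ball_around_atom(self):
        """A single atom at a grid point masks exactly the discrete ball."""
        s = build_toy(
            [[5.0, 5.0, 5.0], [0.0, 0.0, 0.0]], ["C1", "CA"], ["C", "C"],
            [1, 2], ["LIG", "ALA"], ["A", "B"], [True, False],
        )
        grid = DensityGrid(values=np.zeros((11, 11, 11)), voxel_size=1.0)
        site, ref, solv = build_masks(
            s, grid, np.array([True, False]), np.array([False, True]),
            site_r=2.0, ref_r=2.0, solvent_near=3.0, solvent_far=5.0,
        )
        # brute force: voxel centers within 2 A of (5,5,5)
        idx = np.indices((11, 11, 11)).reshape(3, -1).T
        d = np.linalg.norm(idx - [5, 5, 5], axis=1)
        assert site.count == int((d <= 2.0).sum())

    def test_counts_match_brute_force(self, combo, combo_map, masks):
        site, ref, solv = masks
        pts = combo_map.voxel_coords()
        lig = combo.coord[combo.atoms.is_ligand]
        d = np.linalg.norm(pts[:, None, :] - lig[None, :500, :], axis=2)
        # brute-force only over ligand atoms (site mask), full pairwise
        d_all = np.linalg.norm(
            pts[:, None, :] - combo.coord[combo.atoms.is_ligand][None, :, :], axis=2
        ).min(axis=1)
        assert site.count == int((d_all <= 2.0).sum())

    def test_disjoint(self, masks):
        site, ref, solv = masks
        assert not np.any(site.mask & ref.mask)
        assert not np.any(site.mask & solv.mask)
        assert not np.any(ref.mask & solv.mask)

    def test_shared_selection_errors(self, combo, combo_map):
        sel = combo.atoms.is_ligand
        with pytest.raises(MaskOverlapError):
            build_masks(combo, combo_map, sel, sel)

    def test_empty_selection_errors(self, combo, combo_map):
        none = np.zeros(len(combo), dtype=bool)
        with pytest.raises(EmptyMaskError):
            build_masks(combo, combo_map, none, combo.atoms.is_ligand)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            VoxelMask(np.zeros((3, 3, 3), dtype=bool), "site")


def _degenerate_grid_and_masks(site_value, ref_value=10.0, solvent_value=0.0):
    vals = np.full((6, 6, 6), solvent_value, dtype=np.float32)
    vals[1, 1, 1] = site_value
    vals[4, 4, 4] = ref_value
    grid = DensityGrid(values=vals, voxel_size=1.0)
    site = np.zeros((6, 6, 6), dtype=bool)
    site[1, 1, 1] = True
    ref = np.zeros((6, 6, 6), dtype=bool)
    ref[4, 4, 4] = True
    solv = np.zeros((6, 6, 6), dtype=bool)
    solv[:, :, 5] = True
    return grid, VoxelMask(site, "site"), VoxelMask(ref, "reference"), VoxelMask(solv, "solvent")


class TestOccupancy:
    def test_exact_zero(self):
        """Site maximum at the solvent floor gives exactly 0."""
        grid, site, ref, solv = _degenerate_grid_and_masks(site_value=0.0)
        assert occupancy(grid, site, ref, solv).occupancy == 0.0

    def test_exact_one(self):
        """Site maximum equal to the reference maximum gives exactly 1."""
        grid, site, ref, solv = _degenerate_grid_and_masks(site_value=10.0)
        assert occupancy(grid, site, ref, solv).occupancy == 1.0

    def test_degenerate_reference_errors(self):
        grid, site, ref, solv = _degenerate_grid_and_masks(5.0, ref_value=0.0)
        with pytest.raises(DegenerateReferenceError):
            occupancy(grid, site, ref, solv)

    def test_affine_invariance(self, combo_map, masks):
        """occupancy(a v + b) == occupancy(v) for any a > 0."""
        site, ref, solv = masks
        base = occupancy(combo_map, site, ref, solv).occupancy
        rng = np.random.default_rng(3)
        for a, b in [(2.5, 0.0), (0.3, 7.0), (11.0, -4.0)]:
            scaled = DensityGrid(
                values=a * combo_map.values + b,
                voxel_size=combo_map.voxel_size,
                origin=combo_map.origin,
            )
            assert occupancy(scaled, site, ref, solv).occupancy == pytest.approx(
                base, abs=1e-5
            )

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75, 1.0])
    def test_amplitude_recovery(self, combo, small_spec, masks, alpha):
        """Noise-free generator amplitudes are recovered within +/- 0.05."""
        site, ref, solv = masks
        g = simulate_map(
            combo, small_spec.with_(ligand_amplitude=alpha), ref_range=(306, 313)
        )
        est = occupancy(g, site, ref, solv).occupancy
        assert est == pytest.approx(alpha, abs=0.05)

    def test_monotone_in_amplitude(self, combo, small_spec, masks):
        """More ligand density never lowers the occupancy estimate."""
        site, ref, solv = masks
        estimates = []
        for alpha in (0.0, 0.4, 0.8, 1.2):
            g = simulate_map(
                combo, small_spec.with_(ligand_amplitude=alpha), ref_range=(306, 313)
            )
            estimates.append(occupancy(g, site, ref, solv).occupancy)
        assert all(b >= a for a, b in zip(estimates, estimates[1:]))

    def test_trimmed_max_reduces_noise_variance(self, combo, small_spec, masks):
        """Under heavy voxel noise the 99th-percentile max is steadier across
        seeds than the literal max."""
        site, ref, solv = masks
        spec = small_spec.with_(ligand_amplitude=0.5, noise_sd=2.0)
        plain, trimmed = [], []
        for seed in range(6):
            g = simulate_map(combo, spec.with_(seed=seed), ref_range=(306, 313))
            plain.append(occupancy(g, site, ref, solv).occupancy)
            trimmed.append(
                occupancy(g, site, ref, solv, trimmed_max=True).occupancy
            )
        assert np.std(trimmed) < np.std(plain)


class TestRealSpaceCC:
    def test_self_correlation(self, combo, combo_map, masks):
        """A map simulated from the model correlates ~perfectly with itself."""
        site, ref, solv = masks
        ligs = combo.select(combo.atoms.is_ligand)
        sim = simulate_density(ligs, grid=combo_map, resolution=3.8)
        cc = real_space_cc(ligs, sim, site)
        assert cc >= 0.999

    def test_uniform_map_errors(self, combo, masks):
        site, _, _ = masks
        flat = DensityGrid(
            values=np.ones(site.mask.shape, dtype=np.float32), voxel_size=1.0
        )
        ligs = combo.select(combo.atoms.is_ligand)
        with pytest.raises(UndefinedCorrelationError):
            real_space_cc(ligs, flat, site)

    def test_ranks_true_pose_above_shifted(self, combo, masks):
        """A map simulated from pose 1 prefers pose 1 over a shifted pose 2."""
        site, _, _ = masks
        ligs = combo.select(combo.atoms.is_ligand)
        sim = simulate_density(ligs, resolution=3.8, voxel_size=1.0, padding=8.0)
        shifted = ligs.copy()
        c = shifted.atoms.coord.copy()
        c += np.array([2.5, 1.0, 0.0], dtype=np.float32)
        shifted.atoms.coord = c
        mask_site = VoxelMask(
            np.linalg.norm(
                sim.voxel_coords()[:, None, :] - ligs.coord[None, ::6, :], axis=2
            ).min(axis=1).reshape(sim.shape) <= 3.0,
            "site",
        )
        cc1 = real_space_cc(ligs, sim, mask_site)
        cc2 = real_space_cc(shifted, sim, mask_site)
        assert cc1 > cc2
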