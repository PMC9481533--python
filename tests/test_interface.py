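"""Ligand-interface geometry: buried area, hydrogen bonds, stacking, poses."""

import numpy as np
import pytest

from fibrilstab import (
    buried_area,
    find_hbonds,
    make_fibril,
    make_ligand_column,
    pose_report,
    stacking_metrics,
)
from fibrilstab.errors import (
    ComparabilityError,
    InsufficientColumnError,
    SelectionError,
)
from fibrilstab.geometry import rotation_about_axis
from conftest import build_toy

R_C = 1.70
PROBE = 1.4


@pytest.fixture(scope="module")
def combo(small_spec, small_fibril):
    return make_ligand_column(small_fibril, small_spec)


class TestBuriedArea:
    def test_distant_ligand_buries_nothing(self, small_fibril, small_spec):
        combo = make_ligand_column(small_fibril, small_spec.with_(ligand_count=1),
                                   anchor_y=60.0)
        lig = combo.atoms.is_ligand
        assert buried_area(combo, lig, side="receptor") == pytest.approx(0.0, abs=1.0)

    def test_two_atom_cap_oracle(self):
        """One-atom receptor + one-atom ligand at contact distance match the
        analytic two-sphere cap area."""
        d = 3.0
        s = build_toy([[0, 0, 0], [d, 0, 0]], ["C1", "C2"], ["C", "C"], [1, 2],
                      ["REC", "LIG"], ["A", "B"], [False, True])
        lig = s.atoms.res_name == "LIG"
        R = R_C + PROBE
        x1 = (d * d) / (2 * d)  # equal radii
        cap = 2 * np.pi * R * (R - x1)
        for side in ("receptor", "ligand"):
            got = buried_area(s, lig, side=side, n_points=3840)
            assert got == pytest.approx(cap, rel=0.01)

    def test_average_is_exact_mean(self, combo):
        lig = combo.atoms.is_ligand
        r = buried_area(combo, lig, side="receptor")
        l = buried_area(combo, lig, side="ligand")
        a = buried_area(combo, lig, side="average")
        assert a == pytest.approx(0.5 * (r + l), abs=1e-9)

    def test_cleft_ligand_buries_receptor_area(self, combo):
        """A ligand column in the inter-protofilament cleft buries real area."""
        lig = combo.atoms.is_ligand
        assert buried_area(combo, lig, side="receptor") > 100.0

    def test_empty_selection_errors(self, combo):
        with pytest.raises(SelectionError):
            buried_area(combo, np.zeros(len(combo), dtype=bool))


class TestHBonds:
    def test_far_pair_empty(self):
        s = build_toy([[0, 0, 0], [10, 0, 0]], ["O", "N"], ["O", "N"], [1, 2],
                      ["GLY", "ALA"], ["A", "B"])
        assert find_hbonds(s, s.atoms.res_id == 1, s.atoms.res_id == 2) == []

    def test_constructed_geometry_single_bond(self):
        """O-H...O at 2.9 A / 165 deg yields exactly one hydrogen bond."""
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([0.96, 0.0, 0.0])
        theta = np.deg2rad(180.0 - 165.0)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # acceptor along the 165-deg D-H...A direction at |A-D| = 2.9
        lo, hi = 0.5, 4.0
        for _ in range(60):
            t = 0.5 * (lo + hi)
            if np.linalg.norm(h + t * direction - d) < 2.9:
                lo = t
            else:
                hi = t
        acc = h + t * direction
        s = build_toy([d, h, acc], ["OG", "HG", "O"], ["O", "H", "O"],
                      [1, 1, 2], ["SER", "SER", "GLY"], ["A", "A", "B"])
        bonds = find_hbonds(s, s.atoms.res_id == 1, s.atoms.res_id == 2)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-3)
        assert bonds[0].angle == pytest.approx(165.0, abs=0.5)

    def test_angle_cutoff_rejects_bent_bond(self):
        """Same heavy atoms but a ~90-deg D-H...A angle is rejected."""
        s = build_toy(
            [[0, 0, 0], [0.96, 0, 0], [0.96, 2.7, 0]],
            ["OG", "HG", "O"], ["O", "H", "O"], [1, 1, 2],
            ["SER", "SER", "GLY"], ["A", "A", "B"],
        )
        assert find_hbonds(s, s.atoms.res_id == 1, s.atoms.res_id == 2) == []

    def test_heavy_atom_models_use_distance_only(self):
        s = build_toy([[0, 0, 0], [2.9, 0, 0]], ["N", "O"], ["N", "O"],
                      [1, 2], ["LYS", "GLY"], ["A", "B"])
        bonds = find_hbonds(s, s.atoms.res_id == 1, s.atoms.res_id == 2)
        assert len(bonds) == 1
        assert bonds[0].angle is None
        assert bonds[0].donor_label.startswith("A:LYS1")  # N preferred as donor

    def test_swap_symmetry(self, combo):
        """Swapping the selections re-derives the same donor/acceptor pairs."""
        lig = combo.atoms.is_ligand
        fwd = find_hbonds(combo, lig, ~lig)
        rev = find_hbonds(combo, ~lig, lig)
        key = lambda bonds: {
            frozenset((b.donor_index, b.acceptor_index)) for b in bonds
        }
        assert key(fwd) == key(rev)

    def test_overlapping_selections_error(self, combo):
        lig = combo.atoms.is_ligand
        with pytest.raises(SelectionError):
            find_hbonds(combo, lig, lig)


class TestStacking:
    def test_ideal_column(self, small_fibril, small_spec):
        """An unsheared column at 4.8 A: all separations 4.8, tilt 0."""
        spec = small_spec.with_(twist=0.0)
        combo = make_ligand_column(make_fibril(spec), spec)
        prof = stacking_metrics(combo)
        np.testing.assert_allclose(prof.pair_table["separation"], 4.8, atol=1e-4)
        np.testing.assert_allclose(prof.pair_table["tilt"], 0.0, atol=1e-4)
        for lab in prof.ring_labels:
            np.testing.assert_allclose(prof.pair_table[f"sep_{lab}"], 4.8, atol=1e-4)

    def test_curved_stack_signature(self, small_spec):
        """Compressing the solvent edge to 3.5 A widens the fibril face."""
        spec = small_spec.with_(twist=0.0, solvent_edge_compression=3.5)
        combo = make_ligand_column(make_fibril(spec), spec)
        prof = stacking_metrics(combo)
        assert prof.solvent_ring == "RD"
        assert prof.fibril_ring == "RA"
        assert prof.mean_solvent_face == pytest.approx(3.5, abs=1e-3)
        assert prof.mean_fibril_face > 4.8
        assert prof.mean_tilt > 1.0  # the stack curves

    def test_rigid_transform_invariance(self, combo):
        """A rigidly moved column reports the same profile."""
        prof0 = stacking_metrics(combo)
        moved = combo.copy()
        R = rotation_about_axis([1, 1, 0], 35.0)
        c = moved.atoms.coord.copy() @ np.asarray(R.T, dtype=np.float32)
        c += np.array([5.0, -3.0, 2.0], dtype=np.float32)
        moved.atoms.coord = c
        moved.axis = R @ combo.axis
        prof1 = stacking_metrics(moved, axis=moved.axis)
        np.testing.assert_allclose(
            prof1.pair_table["separation"], prof0.pair_table["separation"], atol=1e-3
        )
        np.testing.assert_allclose(
            prof1.pair_table["tilt"], prof0.pair_table["tilt"], atol=0.05
        )

    def test_single_ligand_errors(self, small_fibril, small_spec):
        combo = make_ligand_column(small_fibril, small_spec.with_(ligand_count=1))
        with pytest.raises(InsufficientColumnError):
            stacking_metrics(combo)


class TestPoseReport:
    @pytest.fixture()
    def poses(self, small_spec):
        spec = small_spec.with_(ligand_count=1)
        bound = make_ligand_column(make_fibril(spec), spec)
        rng = np.random.default_rng(11)
        out = [bound]
        for k in range(3):
            p = bound.copy()
            m = p.atoms.is_ligand
            c = p.atoms.coord.copy()
            c[m] += rng.normal(0, 0.8, size=(int(m.sum()), 3)).astype(np.float32)
            p.atoms.coord = c
            out.append(p)
        return out

    def test_bound_pose_dominates_distant_pose(self, small_spec):
        spec = small_spec.with_(ligand_count=1)
        bound = make_ligand_column(make_fibril(spec), spec)
        far = bound.copy()
        m = far.atoms.is_ligand
        c = far.atoms.coord.copy()
        c[m] += np.array([40.0, 0.0, 0.0], dtype=np.float32)
        far.atoms.coord = c
        rep = pose_report([far, bound], ligand_name="LIG")
        best = rep.iloc[0]
        worst = rep.iloc[1]
        assert best["pose"] == 1
        assert best["buried_area"] > worst["buried_area"]
        assert best["complementarity"] >= worst["complementarity"]

    def test_unperturbed_pose_ranks_first_by_cc(self, poses, small_spec):
        """Against a map simulated from the true pose, the true pose wins."""
        from fibrilstab import simulate_map
        from fibrilstab.density import build_masks, backbone_range_selection

        spec = small_spec.with_(ligand_count=1)
        grid = simulate_map(poses[0], spec, ref_range=(306, 313))
        site_sel = poses[0].atoms.is_ligand
        ref_sel = backbone_range_selection(poses[0], 306, 313)
        site, _, _ = build_masks(poses[0], grid, site_sel, ref_sel)
        rep = pose_report(poses, ligand_name="LIG", grid=grid, site_mask=site)
        assert rep.iloc[0]["pose"] == 0
        assert rep.attrs["rank_rule"]

    def test_differing_receptors_error(self, poses):
        other = poses[0].copy()
        c = other.atoms.coord.copy()
        c[~other.atoms.is_ligand] += np.float32(1.5)
        other.atoms.coord = c
        with pytest.raises(ComparabilityError):
            pose_report([poses[0], other], ligand_name="LIG")
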