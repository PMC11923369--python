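import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pincermd import (PincerSpec, domain_map_for, generate_pincer_trajectory,
                      interdomain_distances, radius_of_gyration, rmsd_series,
                      rmsf, sasa, superpose)
from pincermd.metrics import golden_spiral_points, VDW_RADII

from conftest import make_trajectory
from oracles import min_rmsd_rotation_grid, rg_direct, sasa_dense

RNG = np.random.default_rng(20240915)


class TestSuperpose:
    def test_rigid_copy_has_zero_rmsd(self):
        pts = RNG.standard_normal((10, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 1.0])
        r, t, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_two_point_analytic_case(self):
        mobile = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        reference = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        _, _, rmsd = superpose(mobile, reference)
        assert rmsd == pytest.approx(0.5, abs=1e-9)
        grid = min_rmsd_rotation_grid(mobile, reference)
        assert rmsd == pytest.approx(grid, abs=1e-3)

    def test_reflection_not_matched_by_proper_rotation(self):
        # a chiral 4-point set and its mirror image
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.5, 0], [0, 0, 2.0]])
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        r, _, rmsd = superpose(mirrored, pts)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1
        grid = min_rmsd_rotation_grid(mirrored, pts, n=40)
        # Kabsch is optimal: no grid rotation can beat it, and a dense grid
        # should come close to it
        assert rmsd <= grid + 1e-9
        assert grid <= rmsd * 1.15

    def test_invariant_to_rigid_pretransform_of_mobile(self):
        pts = RNG.standard_normal((8, 3))
        other = pts + RNG.standard_normal((8, 3)) * 0.3
        _, _, base = superpose(other, pts)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        _, _, moved = superpose(other @ rot.T + 3.0, pts)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((4, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        frame = RNG.standard_normal((6, 3))
        traj = make_trajectory(np.repeat(frame[None], 5, axis=0))
        np.testing.assert_allclose(rmsd_series(traj).values, 0.0, atol=1e-9)

    def test_first_frame_vs_itself_zero(self, small_traj):
        assert rmsd_series(small_traj).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_series_nonnegative(self, small_traj):
        assert np.all(rmsd_series(small_traj).values >= 0)

    def test_pincer_series_periodicity(self, small_spec):
        spec = dataclasses.replace(small_spec, fluctuation_sigma=0.0)
        traj = generate_pincer_trajectory(spec)
        series = rmsd_series(traj).values
        np.testing.assert_allclose(series[spec.period:], series[:-spec.period],
                                   atol=1e-6)

    def test_rigid_noiseless_domain_measured_alone_is_zero(self, small_spec):
        spec = dataclasses.replace(small_spec, fluctuation_sigma=0.0)
        traj = generate_pincer_trajectory(spec)
        dmap = domain_map_for(spec)
        # N is neither jaw: rigid body, so fitting and measuring on it is flat
        idx = traj.topology.atom_indices_for_residues(dmap.residues_of("N"))
        series = rmsd_series(traj, selection=idx, fit_selection=idx)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_empty_selection_rejected(self, small_traj):
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(small_traj, selection=np.array([], dtype=int))


class TestRmsf:
    def test_static_trajectory_zero(self):
        frame = RNG.standard_normal((6, 3)) * 5
        traj = make_trajectory(np.repeat(frame[None], 4, axis=0))
        np.testing.assert_allclose(rmsf(traj).values, 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        traj = make_trajectory(RNG.standard_normal((1, 6, 3)))
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj)

    def test_gaussian_noise_recovers_sigma_sqrt3(self):
        # 100 atoms keep the rigid-fit bias sqrt(1 - 6/3N) well below the
        # 3% recovery tolerance
        spec = PincerSpec(n_domains=4, residues_per_domain=25,
                          jaw_pair=("PAZ", "L2"), amplitude=0.0, period=100,
                          fluctuation_sigma=0.5, n_frames=10_000, seed=11)
        traj = generate_pincer_trajectory(spec)
        values = rmsf(traj).values
        assert values.mean() == pytest.approx(0.5 * np.sqrt(3), rel=0.03)

    def test_invariant_to_frame_order_permutation(self, small_traj):
        base = rmsf(small_traj).values
        perm = RNG.permutation(small_traj.n_frames)
        shuffled = make_trajectory(small_traj.coords[perm])
        np.testing.assert_allclose(rmsf(shuffled).values, base, atol=1e-9)


class TestRadiusOfGyration:
    def test_two_unit_masses_two_angstrom_apart(self):
        traj = make_trajectory(np.array([[[0.0, 0, 0], [2.0, 0, 0]]]))
        assert radius_of_gyration(traj).values[0] == pytest.approx(1.0)

    def test_translation_invariance(self, small_traj):
        base = radius_of_gyration(small_traj).values
        moved = make_trajectory(small_traj.coords + np.array([100.0, 0, 0]))
        np.testing.assert_allclose(radius_of_gyration(moved).values, base,
                                   atol=1e-9)

    def test_matches_direct_formula_oracle(self):
        coords = RNG.standard_normal((1, 10, 3)) * 4
        masses = RNG.uniform(1, 12, size=10)
        traj = make_trajectory(coords, masses=masses)
        expected = rg_direct(coords[0], masses)
        assert radius_of_gyration(traj).values[0] == pytest.approx(
            expected, abs=1e-12)


class TestInterdomainDistances:
    def test_two_single_atom_domains(self):
        from pincermd import DomainMap
        traj = make_trajectory(np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]]))
        dmap = DomainMap(protein="toy", entries=(("A", 1, 1), ("B", 2, 2)))
        series = interdomain_distances(traj, dmap)
        assert series.get("A", "B").values[0] == pytest.approx(5.0)
        assert series.get("B", "A").values[0] == pytest.approx(5.0)

    def test_non_jaw_pair_constant(self, small_spec, small_map):
        spec = dataclasses.replace(small_spec, fluctuation_sigma=0.0)
        traj = generate_pincer_trajectory(spec)
        series = interdomain_distances(traj, small_map).get("N", "L1").values
        assert series.max() - series.min() == pytest.approx(0.0, abs=1e-9)

    def test_triangle_inequality_per_frame(self, small_traj, small_map):
        dm = interdomain_distances(small_traj, small_map)
        names = small_map.domain_names
        for i, a in enumerate(names):
            for j, b in enumerate(names[i + 1:], start=i + 1):
                for c in names[j + 1:]:
                    ab = dm.get(a, b).values
                    bc = dm.get(b, c).values
                    ac = dm.get(a, c).values
                    assert np.all(ac <= ab + bc + 1e-9)


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        total, per_res = sasa(np.zeros((1, 3)), ["C"])
        expected = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.01)
        assert per_res[0] == pytest.approx(total)

    def test_fully_separated_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        total, _ = sasa(coords, ["C", "O"])
        lone_c, _ = sasa(np.zeros((1, 3)), ["C"])
        lone_o, _ = sasa(np.zeros((1, 3)), ["O"])
        assert total == pytest.approx(lone_c + lone_o, rel=1e-9)

    def test_overlapping_pair_matches_dense_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0], [1.0, 2.0, 0.5]])
        elements = ["C", "N", "O"]
        total, _ = sasa(coords, elements, n_points=960)
        radii = [VDW_RADII[e] for e in elements]
        dense = sasa_dense(coords, radii, probe=1.4)
        assert total == pytest.approx(dense, rel=0.02)

    def test_monotone_nonincreasing_with_added_occluder(self):
        base = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        occluded = np.vstack([base, [[1.5, 1.5, 0.0]]])
        t_base, _ = sasa(base, ["C", "C"])
        t_occ, per_res = sasa(occluded, ["C", "C", "C"])
        assert per_res[0] <= t_base / 2 + 1e-9
        first_two = per_res[0] + per_res[1]
        assert first_two <= t_base + 1e-9

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa(np.zeros((1, 3)), ["Xx"])

    def test_golden_spiral_points_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01
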