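"""Descriptor primitives against exhaustive / analytic / sampled oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allostate.featurize import (SelectionError, SelectionGroup, Topology,
                                 Trajectory, com_distance,
                                 count_cross_contacts, default_selections,
                                 featurize_frame, featurize_trajectory,
                                 select_frame_indices, shrake_rupley_sasa)
from allostate.synthetic import ToyDimerSpec, generate_toy_trajectory


def brute_force_contacts(a, b, cutoff=4.5):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return int((d < cutoff).sum())


def mc_sasa(coords, radii, report, probe=1.4, n_dirs=60_000, seed=0):
    """Monte-Carlo surface-sampling oracle, independent of the
    golden-spiral lattice used by the implementation."""
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    total = 0.0
    for i in report:
        dirs = rng.normal(size=(n_dirs, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * dirs
        free = np.ones(n_dirs, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= (np.linalg.norm(pts - coords[j], axis=1)
                     >= expanded[j])
        total += 4.0 * math.pi * expanded[i] ** 2 * free.mean()
    return total


class TestContacts:
    def test_single_pair_below_cutoff(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[4.0, 0.0, 0.0]])
        assert count_cross_contacts(a, b) == 1

    def test_pair_exactly_at_cutoff_excluded(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[4.5, 0.0, 0.0]])
        assert count_cross_contacts(a, b) == 0

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(25):
            a = rng.uniform(0, 10, (10, 3))
            b = rng.uniform(0, 10, (10, 3))
            assert count_cross_contacts(a, b) == brute_force_contacts(a, b)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 8, (15, 3))
        b = rng.uniform(0, 8, (12, 3))
        assert count_cross_contacts(a, b) == count_cross_contacts(b, a)

    def test_cutoff_monotonicity(self, rng):
        a = rng.uniform(0, 8, (15, 3))
        b = rng.uniform(0, 8, (15, 3))
        counts = [count_cross_contacts(a, b, cutoff)
                  for cutoff in (2.0, 3.0, 4.5, 6.0, 9.0)]
        assert counts == sorted(counts)

    def test_empty_group_rejected(self):
        with pytest.raises(SelectionError, match="non-empty"):
            count_cross_contacts(np.empty((0, 3)), np.ones((1, 3)))


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        # r = 1.6 plus probe 1.4: accessible surface is a sphere of
        # radius 3.0 with area 4*pi*9 = 113.097...
        coords = np.zeros((1, 3))
        radii = np.array([1.6])
        area = shrake_rupley_sasa(coords, radii, np.array([0]),
                                  n_sphere_points=960)
        assert area == pytest.approx(4 * math.pi * 9.0, rel=0.01)

    def test_caged_atom_has_zero_area(self):
        # surround a central atom with a tight cage of neighbours on a
        # fine sphere so no probe position survives
        cage_dirs = []
        for theta in np.linspace(0, math.pi, 10):
            for phi in np.linspace(0, 2 * math.pi, 20, endpoint=False):
                cage_dirs.append([math.sin(theta) * math.cos(phi),
                                  math.sin(theta) * math.sin(phi),
                                  math.cos(theta)])
        cage = 2.0 * np.unique(np.round(cage_dirs, 6), axis=0)
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.full(len(coords), 1.7)
        area = shrake_rupley_sasa(coords, radii, np.array([0]))
        assert area == 0.0

    def test_two_overlapping_spheres_match_analytic_caps(self):
        # two equal spheres: each expanded sphere of radius R loses a cap
        # of height R - d/2, area 2*pi*R*h
        r, probe, d = 1.7, 1.4, 2.5
        R = r + probe
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        radii = np.array([r, r])
        expected = 2 * (4 * math.pi * R ** 2
                        - 2 * math.pi * R * (R - d / 2))
        area = shrake_rupley_sasa(coords, radii, np.array([0, 1]),
                                  n_sphere_points=960)
        assert area == pytest.approx(expected, rel=0.02)

    def test_cluster_matches_monte_carlo_oracle(self, rng):
        coords = rng.uniform(0, 5, (6, 3))
        radii = rng.uniform(1.4, 1.9, 6)
        report = np.array([0, 2, 4])
        oracle = mc_sasa(coords, radii, report)
        area = shrake_rupley_sasa(coords, radii, report,
                                  n_sphere_points=960)
        assert area == pytest.approx(oracle, rel=0.02)

    def test_occluder_never_increases_area(self, rng):
        coords = rng.uniform(0, 6, (5, 3))
        radii = np.full(5, 1.7)
        report = np.arange(5)
        base = shrake_rupley_sasa(coords, radii, report)
        with_extra = shrake_rupley_sasa(
            np.vstack([coords, coords.mean(0, keepdims=True)]),
            np.append(radii, 1.7), report)
        assert with_extra <= base + 1e-9

    def test_convergence_with_point_count(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.2, 0.0, 0.0]])
        radii = np.array([1.6, 1.6])
        dense = shrake_rupley_sasa(coords, radii, np.array([0]),
                                   n_sphere_points=7680)
        coarse = shrake_rupley_sasa(coords, radii, np.array([0]),
                                    n_sphere_points=240)
        mid = shrake_rupley_sasa(coords, radii, np.array([0]),
                                 n_sphere_points=960)
        assert abs(mid - dense) <= abs(coarse - dense) + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="16"):
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.5]),
                               np.array([0]), n_sphere_points=8)


class TestComDistance:
    def test_identical_groups_give_zero(self):
        c = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        m = np.array([2.0, 3.0])
        assert com_distance(c, m, c, m) == 0.0

    def test_hand_arithmetic(self):
        a = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[5.0, 0, 0]])
        assert com_distance(a, np.ones(2), b, np.ones(1)) \
            == pytest.approx(4.0)

    def test_matches_independent_centroid_computation(self, rng):
        a, b = rng.uniform(0, 10, (5, 3)), rng.uniform(0, 10, (5, 3))
        ma, mb = rng.uniform(1, 20, 5), rng.uniform(1, 20, 5)
        com_a = (ma[:, None] * a).sum(0) / ma.sum()
        com_b = (mb[:, None] * b).sum(0) / mb.sum()
        expected = float(np.linalg.norm(com_a - com_b))
        assert com_distance(a, ma, b, mb) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            com_distance(np.zeros((1, 3)), np.array([0.0]),
                         np.ones((1, 3)), np.array([1.0]))


class TestSelections:
    def test_hydrogens_rejected_in_descriptor_groups(self):
        top = Topology(atom_names=np.array(["CA", "HA"], dtype=object),
                       elements=np.array(["C", "H"], dtype=object),
                       residue_numbers=np.array([100, 100]),
                       residue_names=np.array(["GLY", "GLY"], dtype=object),
                       monomer_ids=np.array(["m", "m"], dtype=object),
                       masses=np.array([12.0, 1.0]),
                       radii=np.array([1.7, 1.2]))
        group = SelectionGroup("g", "m", ((100, 100),), rule="atom-names",
                               atom_names=("CA", "HA"))
        with pytest.raises(SelectionError, match="hydrogen"):
            group.resolve(top)
        heavy = SelectionGroup("g", "m", ((100, 100),))
        assert list(heavy.resolve(top)) == [0]

    def test_empty_group_named_in_error(self, toy_spec):
        traj = generate_toy_trajectory(toy_spec, "A", 1)
        group = SelectionGroup("nothing-here", "buckled", ((900, 900),))
        with pytest.raises(SelectionError, match="nothing-here"):
            group.resolve(traj.topology)


class TestFrameSelection:
    @pytest.mark.parametrize("production_ns,interval,stride,expected", [
        (80.0, 20.0, 20.0, 4000),
        (200.0, 20.0, 100.0, 2000),
        (100.0, 20.0, 20.0, 5000),
    ])
    def test_stride_arithmetic(self, production_ns, interval, stride,
                               expected):
        n = int(production_ns * 1000 / interval)
        kept = select_frame_indices(n, interval, stride, discard_ns=0.0)
        assert len(kept) == expected

    def test_discard_drops_leading_span(self):
        # 100 ns saved every 20 ps with 20 ns discarded leaves an 80 ns
        # production span: 4000 rows
        kept = select_frame_indices(5000, 20.0, 20.0, discard_ns=20.0)
        assert len(kept) == 4000
        assert kept[0] == 1000  # first frame after 20 ns

    def test_incommensurate_stride_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            select_frame_indices(100, 20.0, 30.0, 0.0)

    def test_empty_output_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            select_frame_indices(10, 20.0, 20.0, discard_ns=1.0)


class TestFeaturizeTrajectory:
    def test_single_frame_identity(self, toy_spec):
        traj = generate_toy_trajectory(toy_spec, "A", 1)
        sel = default_selections()
        matrix = featurize_trajectory(traj, sel, discard_ns=0.0,
                                      label="A", n_sphere_points=96)
        direct = featurize_frame(traj.topology, traj.coords[0], sel,
                                 n_sphere_points=96)
        assert len(matrix) == 1
        np.testing.assert_allclose(
            matrix.iloc[0][:8].to_numpy(dtype=float), direct)

    def test_row_count_and_time_order(self, toy_spec):
        traj = generate_toy_trajectory(toy_spec, "I", 20)
        matrix = featurize_trajectory(traj, default_selections(),
                                      stride_ps=40.0, discard_ns=0.0,
                                      label="I", n_sphere_points=96)
        assert len(matrix) == 10
        assert matrix["time_ps"].is_monotonic_increasing

    def test_rigid_motion_invariance(self, toy_spec):
        traj = generate_toy_trajectory(toy_spec, "A", 2)
        sel = default_selections()
        base = np.array([featurize_frame(traj.topology, c, sel)
                         for c in traj.coords])
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        shift = np.array([102.0, -55.0, 33.0])
        moved = traj.coords @ rot.T + shift
        after = np.array([featurize_frame(traj.topology, c, sel)
                          for c in moved])
        # contacts and distances are exact; SASA to lattice resolution
        exact = [0, 1, 4, 5]
        sasa = [2, 3, 6, 7]
        np.testing.assert_allclose(after[:, exact], base[:, exact],
                                   rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(after[:, sasa], base[:, sasa],
                                   rtol=0.02, atol=2.0)

    def test_lid_exposure_drives_sasa(self):
        from allostate.synthetic import StateGeometry
        buried = ToyDimerSpec(rng_seed=2, geometry={
            "A": StateGeometry(lid_burial_fraction=1.0)})
        exposed = ToyDimerSpec(rng_seed=2, geometry={
            "A": StateGeometry(lid_burial_fraction=0.0)})
        sel = default_selections()
        mb = featurize_trajectory(generate_toy_trajectory(buried, "A", 2),
                                  sel, label="A", n_sphere_points=240)
        me = featurize_trajectory(generate_toy_trajectory(exposed, "A", 2),
                                  sel, label="A", n_sphere_points=240)
        assert (me["lid_sasa_1"] > mb["lid_sasa_1"]).all()
        assert (me["lid_sasa_2"] > mb["lid_sasa_2"]).all()

    def test_pbc_wrapped_input_rejected(self, toy_spec):
        traj = generate_toy_trajectory(toy_spec, "A", 2)
        coords = traj.coords.copy()
        coords[1, 0] += 600.0
        with pytest.raises(ValueError, match="span"):
            Trajectory(traj.topology, coords, traj.frame_interval_ps)
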