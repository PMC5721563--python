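"""Procrustes geometry against brute-force oracles and exact identities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import valvemorph as vm
from valvemorph.exceptions import DegenerateConfigurationError, ShapeMismatchError
from valvemorph.gpa import _center_scale_stack

from conftest import grid_min_distance, grid_slide_residual, tiny_generator

QUAD = np.array([[0.0, 0.0, 0.0], [1.0, 0.1, -0.2], [0.3, 1.2, 0.4], [-0.5, 0.6, 1.0]])


def _rot(axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


class TestCenterAndScale:
    def test_centers_and_unit_size(self):
        cfg = vm.LandmarkConfiguration(QUAD + 7.5, k_fixed=4)
        out, size = vm.center_and_scale(cfg)
        assert np.abs(out.coords.mean(axis=0)).max() < 1e-10
        assert np.sqrt((out.coords**2).sum()) == pytest.approx(1.0, abs=1e-10)
        assert size == pytest.approx(vm.centroid_size(QUAD))

    def test_identity_on_normalized_input(self):
        normed, _ = vm.center_and_scale(QUAD)
        again, size = vm.center_and_scale(normed)
        np.testing.assert_allclose(again, normed, atol=1e-14)
        assert size == pytest.approx(1.0)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateConfigurationError):
            vm.center_and_scale(np.ones((4, 3)))


class TestOptimalRotation:
    def test_recovers_known_rotation(self):
        A, _ = vm.center_and_scale(QUAD)
        R_true = _rot("z", np.pi / 2)
        B = A @ R_true
        R = vm.optimal_rotation(A, B)
        np.testing.assert_allclose(R, R_true, atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_identity_for_equal_inputs(self):
        A, _ = vm.center_and_scale(QUAD)
        np.testing.assert_allclose(vm.optimal_rotation(A, A), np.eye(3), atol=1e-12)

    def test_mirror_target_matches_grid_oracle(self):
        """Best proper rotation onto a reflected copy: no closed shortcut,
        so compare the achieved distance to refined grid search."""
        A, _ = vm.center_and_scale(QUAD)
        B = A.copy()
        B[:, 0] = -B[:, 0]
        R = vm.optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0)
        achieved = float(np.sqrt(((A @ R - B) ** 2).sum()))
        oracle = grid_min_distance(A, B)
        assert achieved == pytest.approx(oracle, abs=1e-6)


class TestProcrustesDistance:
    def test_zero_for_identical_and_similarity_transformed(self):
        assert vm.procrustes_distance(QUAD, QUAD, align_first=False) == 0.0
        assert vm.procrustes_distance(QUAD, QUAD) < 1e-12
        moved = 2.5 * QUAD @ _rot("y", 0.7) + np.array([1.0, -2.0, 3.0])
        assert vm.procrustes_distance(QUAD, moved, align_first=True) < 1e-12

    def test_matches_grid_oracle_on_fixed_configurations(self):
        rng = np.random.default_rng(3)
        other = QUAD + rng.normal(scale=0.3, size=QUAD.shape)
        d = vm.procrustes_distance(QUAD, other, align_first=True)
        A, _ = vm.center_and_scale(QUAD)
        B, _ = vm.center_and_scale(other)
        assert d == pytest.approx(grid_min_distance(B, A), abs=1e-6)

    def test_mismatched_k_raises(self):
        with pytest.raises(ShapeMismatchError):
            vm.procrustes_distance(QUAD, QUAD[:3])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 5, 3))
        dab = vm.procrustes_distance(a, b)
        dba = vm.procrustes_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-8)
        # triangle inequality on jointly aligned (align_first=False) shapes
        stack, _ = _center_scale_stack(np.stack([a, b, c]))
        d = lambda i, j: vm.procrustes_distance(stack[i], stack[j], align_first=False)
        assert d(0, 2) <= d(0, 1) + d(1, 2) + 1e-12


class TestMirror:
    def test_involution_and_single_axis(self):
        cfg = vm.LandmarkConfiguration(QUAD, k_fixed=4)
        m = vm.mirror_configuration(cfg, "x")
        np.testing.assert_array_equal(
            vm.mirror_configuration(m, "x").coords, cfg.coords
        )
        np.testing.assert_allclose(
            vm.mirror_configuration(np.array([[1.0, 2.0, 3.0]] * 3), "x"),
            [[-1, 2, 3]] * 3,
        )

    def test_mirror_distance_zero_for_config_on_mirror_plane(self):
        # every landmark lies on the x=0 plane, so the x-mirror fixes
        # each point individually (internal mirror plane with identity
        # correspondence)
        sym = np.array(
            [[0, 0, 1], [0, 1, 0.3], [0, -1, 0.3], [0, 2, -0.5]], dtype=float
        )
        m = vm.mirror_configuration(sym, "x")
        assert vm.procrustes_distance(sym, m, align_first=True) < 1e-8

    def test_mirror_distance_matches_grid_oracle_for_chiral_config(self):
        A, _ = vm.center_and_scale(QUAD)
        B = vm.mirror_configuration(A, "z")
        d = vm.procrustes_distance(A, B, align_first=True)
        assert d == pytest.approx(grid_min_distance(B, A), abs=1e-6)
        assert d > 0.1  # genuinely chiral: reflection is not recoverable


class TestSliding:
    def _topology(self):
        # 1 fixed + 1 curve semilandmark (indices into a 6-point config)
        return vm.SemilandmarkTopology(
            k_fixed=1, curve=((1, 2, 3),), surface=((4, (0, 2, 3, 5)),)
        )

    def test_zero_displacement_at_reference(self, rng):
        shape = rng.normal(size=(6, 3))
        topo = self._topology()
        out = vm.slide_semilandmarks(shape, shape, topo)
        np.testing.assert_array_equal(out, shape)

    def test_curve_point_projects_onto_tangent(self):
        shape = np.array(
            [[0, 0, 0], [1, 0.3, 0], [1, -1, 0], [1, 1, 0], [2, 0, 0], [3, 0, 0]],
            dtype=float,
        )
        ref = shape.copy()
        ref[1] = [1, 0, 0]
        out = vm.slide_semilandmarks(shape, ref, self._topology())
        np.testing.assert_allclose(out[1], [1, 0, 0], atol=1e-12)

    def test_residual_matches_grid_search(self, rng):
        """Post-slide residuals equal the subspace minimum (curve and surface)."""
        shape = rng.normal(size=(6, 3))
        ref = shape + rng.normal(scale=0.3, size=(6, 3))
        topo = self._topology()
        out = vm.slide_semilandmarks(shape, ref, topo)
        # curve point: tangent direction from its chain neighbors
        t = shape[3] - shape[2]
        t /= np.linalg.norm(t)
        res_curve = float(np.linalg.norm(out[1] - ref[1]))
        assert res_curve == pytest.approx(
            grid_slide_residual(shape[1], ref[1], t[None]), abs=1e-6
        )
        # surface point: best-fit plane of its neighbors
        P = shape[[0, 2, 3, 5]]
        Pc = P - P.mean(axis=0)
        _, _, Vt = np.linalg.svd(Pc)
        res_surf = float(np.linalg.norm(out[4] - ref[4]))
        assert res_surf == pytest.approx(
            grid_slide_residual(shape[4], ref[4], Vt[:2]), abs=1e-6
        )

    def test_fixed_landmarks_bit_exact(self, rng):
        left, _, _, _ = vm.generate_dataset(tiny_generator(seed=2))
        stack = left.coords[:8]
        ref = stack.mean(axis=0)
        out = vm.slide_semilandmarks(stack, ref, left.topology)
        kf = left.topology.k_fixed
        assert np.array_equal(out[:, :kf], stack[:, :kf])


class TestGPA:
    def test_exact_registration_of_similarity_copies(self, rng):
        base = QUAD
        coords = []
        for _ in range(3):
            R = _rot("z", rng.uniform(0, 2 * np.pi)) @ _rot("x", rng.uniform(0, np.pi))
            coords.append((0.5 + rng.random()) * base @ R + rng.normal(size=3))
        labels = pd.DataFrame(
            {
                "specimen_id": ["a", "b", "c"],
                "species": "s",
                "side": "left",
                "replicate": [1, 2, 3],
                "ecomorph": "gliding",
            }
        )
        data = vm.SpecimenSet(np.stack(coords), labels, vm.SemilandmarkTopology(k_fixed=4))
        aligned = vm.gpa_align(data, slide=False)
        assert aligned.converged
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.sqrt(((aligned.shapes[i] - aligned.shapes[j]) ** 2).sum())
                assert d < 1e-8

    def test_two_shape_alignment_matches_closed_form(self):
        """Consensus of two shapes = their aligned average; the total SS
        halves the squared pairwise Procrustes distance."""
        tri1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        tri2 = np.array([[0, 0, 0], [1.2, 0.1, 0], [0.2, 0.8, 0.3]], dtype=float)
        labels = pd.DataFrame(
            {
                "specimen_id": ["a", "b"],
                "species": "s",
                "side": "left",
                "replicate": [1, 2],
                "ecomorph": "gliding",
            }
        )
        data = vm.SpecimenSet(
            np.stack([tri1, tri2]), labels, vm.SemilandmarkTopology(k_fixed=3)
        )
        aligned = vm.gpa_align(data, slide=False)
        d_pair = np.sqrt(((aligned.shapes[0] - aligned.shapes[1]) ** 2).sum())
        # direct two-shape orthogonal Procrustes
        A, _ = vm.center_and_scale(tri1)
        B, _ = vm.center_and_scale(tri2)
        d_direct = float(np.sqrt(((B @ vm.optimal_rotation(B, A) - A) ** 2).sum()))
        assert d_pair == pytest.approx(d_direct, abs=1e-6)
        mean = aligned.shapes.mean(axis=0)
        ss = float(((aligned.shapes - mean[None]) ** 2).sum())
        assert ss == pytest.approx(d_pair**2 / 2, rel=1e-6)

    def test_alignment_invariant_to_specimen_order(self):
        left, _, _, _ = vm.generate_dataset(tiny_generator(seed=4))
        aligned = vm.gpa_align(left, slide=True)
        perm = np.random.default_rng(0).permutation(left.n)
        aligned_p = vm.gpa_align(left.subset(perm), slide=True)
        d = lambda S: np.sqrt(
            ((S[:, None] - S[None]) ** 2).sum(axis=(2, 3))
        )
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            d(aligned.shapes), d(aligned_p.shapes)[np.ix_(inv, inv)], atol=1e-6
        )

    def test_sliding_pass_never_increases_ss(self, tiny_aligned):
        for before, after in tiny_aligned.ss_history:
            assert after <= before + 1e-12

    def test_unit_size_and_centering_postconditions(self, tiny_aligned):
        sizes = np.sqrt((tiny_aligned.shapes**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-10)
        centroids = tiny_aligned.shapes.mean(axis=1)
        assert np.abs(centroids).max() < 1e-10


class TestAggregation:
    def test_average_replicates_counts_and_identity(self, tiny_aligned):
        avg = vm.average_replicates(tiny_aligned)
        n_valves = tiny_aligned.labels.groupby(["specimen_id", "side"]).ngroups
        assert avg.n == n_valves
        assert (avg.labels["replicate"] == 1).all()
        sizes = np.sqrt((avg.shapes**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-10)

    def test_identical_replicates_pass_through(self):
        shape, _ = vm.center_and_scale(QUAD)
        labels = pd.DataFrame(
            {
                "specimen_id": ["a", "a", "b"],
                "species": "s",
                "side": "left",
                "replicate": [1, 2, 1],
                "ecomorph": "gliding",
            }
        )
        aligned = vm.AlignedSet(
            shapes=np.stack([shape, shape, shape]),
            centroid_sizes=np.ones(3),
            labels=labels,
            topology=vm.SemilandmarkTopology(k_fixed=4),
            mean_shape=shape,
            iterations_run=1,
            converged=True,
        )
        avg = vm.average_replicates(aligned)
        assert avg.n == 2  # replicate counts {2, 1} -> 2 valves
        np.testing.assert_allclose(avg.shapes[0], shape, atol=1e-12)

    def test_species_means_order_and_symmetry(self, tiny_aligned):
        order = sorted(tiny_aligned.labels["species"].unique())
        means = vm.species_means(tiny_aligned, order)
        assert means.species == order
        assert means.shapes.shape[0] == len(order)
        assert means.n_specimens.sum() == tiny_aligned.n
        with pytest.raises(KeyError):
            vm.species_means(tiny_aligned, order + ["missing_sp"])
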