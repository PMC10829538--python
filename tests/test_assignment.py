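import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pemlearn import synthetic
from pemlearn.assignment import (
    OptimizationConfig,
    SignedPermutation,
    apply_signed_permutation,
    assign_geometry_pem,
    em_optimize,
    enumerate_signed_permutations,
    global_gauge_mode,
    linear_assign,
    multistart_select,
    pem_objective,
    two_opt_refine,
)


def random_symmetric(rng, n):
    A = rng.normal(size=(n, n))
    return 0.5 * (A + A.T)


signed_perms = st.integers(0, 2**31 - 1).map(
    lambda s: synthetic.random_signed_permutation(np.random.default_rng(s), 4)
)


class TestSignedPermutationGroup:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(signed_perms, signed_perms)
    def test_composition_matches_matrix_product(self, a, b):
        assert np.allclose(a.compose(b).matrix(), a.matrix() @ b.matrix())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(signed_perms)
    def test_inverse_is_transpose(self, s):
        assert np.allclose(s.inverse().matrix(), s.matrix().T)
        assert s.compose(s.inverse()) == SignedPermutation.identity(4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SignedPermutation((0, 0, 1), (1, 1, 1))
        with pytest.raises(ValueError):
            SignedPermutation((0, 1), (1, 2))


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(1, 1), (2, 4), (3, 24), (4, 192)])
    def test_counts_match_group_order(self, n, count):
        elems = list(enumerate_signed_permutations(n))
        assert len(elems) == count == 2 ** (n - 1) * math.factorial(n)
        mats = {tuple(s.matrix().ravel()) for s in elems}
        assert len(mats) == count  # all distinct as matrices

    def test_gauge_fixed(self):
        assert all(s.signs[0] == 1 for s in enumerate_signed_permutations(3))

    def test_guard_on_large_n(self):
        with pytest.raises(ValueError, match="two-opt"):
            list(enumerate_signed_permutations(9))


class TestApplySignedPermutation:
    def test_identity_leaves_unchanged(self, rng):
        U = random_symmetric(rng, 3)
        assert np.allclose(apply_signed_permutation(U, SignedPermutation.identity(3)), U)

    def test_global_sign_flip_is_gauge(self, rng):
        U = random_symmetric(rng, 4)
        flipped = SignedPermutation(tuple(range(4)), (-1,) * 4)
        assert np.allclose(apply_signed_permutation(U, flipped), U)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(signed_perms, st.integers(0, 2**31 - 1))
    def test_matches_dense_matrix_product(self, S, seed):
        U = random_symmetric(np.random.default_rng(seed), 4)
        M = S.matrix()
        assert np.allclose(apply_signed_permutation(U, S), M.T @ U @ M, atol=1e-12)

    def test_eigenvalues_invariant(self, rng):
        U = random_symmetric(rng, 5)
        S = synthetic.random_signed_permutation(rng, 5)
        assert np.allclose(
            np.linalg.eigvalsh(apply_signed_permutation(U, S)), np.linalg.eigvalsh(U)
        )


class TestLinearAssign:
    def test_identity_dominant(self):
        cost = np.full((3, 3), 10.0) - 9.0 * np.eye(3)
        assert linear_assign(cost) == (0, 1, 2)

    def test_two_by_two_swap(self):
        assert linear_assign(np.array([[10.0, 1.0], [1.0, 10.0]])) == (1, 0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            cost = rng.uniform(size=(5, 5))
            best = min(
                itertools.permutations(range(5)),
                key=lambda p: sum(cost[i, p[i]] for i in range(5)),
            )
            assert linear_assign(cost) == best

    def test_ties_break_lexicographically(self):
        assert linear_assign(np.ones((4, 4))) == (0, 1, 2, 3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            linear_assign(np.array([[np.nan, 1.0], [1.0, 0.0]]))


class TestAssignGeometryPEM:
    def test_exact_match_gives_identity(self, rng):
        U = random_symmetric(rng, 3)
        S, obj = assign_geometry_pem(U, U, mode="full")
        assert S == SignedPermutation.identity(3)
        assert obj == pytest.approx(0.0, abs=1e-20)

    def test_recovers_known_scramble(self, rng):
        U = random_symmetric(rng, 4)
        S_true = synthetic.random_signed_permutation(rng, 4)
        scrambled = apply_signed_permutation(U, S_true)
        # searching S with S^T scrambled S = U recovers the inverse scramble
        S_found, obj = assign_geometry_pem(U, scrambled, mode="full")
        assert obj == pytest.approx(0.0, abs=1e-18)
        assert S_found == S_true.inverse().gauge_fixed()

    def test_full_mode_matches_brute_force(self, rng):
        for _ in range(5):
            A, U = random_symmetric(rng, 3), random_symmetric(rng, 3)
            S, obj = assign_geometry_pem(A, U, mode="full")
            brute = min(enumerate_signed_permutations(3), key=lambda s: pem_objective(A, U, s))
            assert obj == pytest.approx(pem_objective(A, U, brute), abs=1e-12)

    def test_full_never_worse_than_diag_then_signs(self, rng):
        A, U = random_symmetric(rng, 4), random_symmetric(rng, 4)
        _, obj_diag = assign_geometry_pem(A, U, mode="diag-then-signs")
        _, obj_full = assign_geometry_pem(A, U, mode="full")
        assert obj_full <= obj_diag + 1e-15

    def test_guard_on_large_manifold(self, rng):
        A = random_symmetric(rng, 9)
        with pytest.raises(ValueError, match="two-opt"):
            assign_geometry_pem(A, A, mode="full")


class TestTwoOpt:
    def test_global_optimum_is_fixed_point(self, rng):
        A, U = random_symmetric(rng, 3), random_symmetric(rng, 3)
        best = min(enumerate_signed_permutations(3), key=lambda s: pem_objective(A, U, s))
        refined = two_opt_refine(best, lambda s: pem_objective(A, U, s))
        assert pem_objective(A, U, refined) == pytest.approx(pem_objective(A, U, best))

    def test_objective_never_below_exhaustive_optimum(self, rng):
        for _ in range(5):
            A, U = random_symmetric(rng, 3), random_symmetric(rng, 3)
            S2, obj2 = assign_geometry_pem(A, U, mode="two-opt")
            opt = min(pem_objective(A, U, s) for s in enumerate_signed_permutations(3))
            assert obj2 >= opt - 1e-15

    def test_moves_strictly_decrease(self, rng):
        A, U = random_symmetric(rng, 4), random_symmetric(rng, 4)
        start = SignedPermutation.identity(4)
        refined = two_opt_refine(start, lambda s: pem_objective(A, U, s))
        assert pem_objective(A, U, refined) <= pem_objective(A, U, start)


def _small_scramble_problem(model_seed=0, n_geoms=60):
    model = synthetic.make_diabatic_model(3, 2, seed=model_seed)
    coords = synthetic.sample_coords(2, n_geoms, seed=model_seed + 1)
    _, _, U_true = synthetic.evaluate_adiabatic(model, coords)
    scrambled, record = synthetic.scramble(U_true, seed=model_seed + 2)
    return coords, scrambled, record


class TestEMOptimize:
    def test_no_crossing_dataset_is_fixed_point(self):
        # well-separated constant surfaces: energy ordering never changes
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(25, 1))
        E = np.column_stack([0.1 * X[:, 0], 5 + 0.1 * X[:, 0], 10 - 0.1 * X[:, 0]])
        cfg = OptimizationConfig(n_restarts=1, seed=0, repair_rounds=0)
        res = em_optimize(E, "energies", X, cfg)
        assert res.converged
        assert all(s == SignedPermutation.identity(3) for s in res.assignments)

    def test_scramble_recovery_mod_gauge(self):
        coords, scrambled, record = _small_scramble_problem(0, 60)
        cfg = OptimizationConfig(n_restarts=1, seed=11, mode="full")
        res = em_optimize(scrambled, "pems", coords, cfg)
        _, frac = global_gauge_mode(list(res.assignments), list(record.applied))
        assert frac >= 0.95

    def test_same_seed_identical_result(self):
        coords, scrambled, _ = _small_scramble_problem(1, 40)
        cfg = OptimizationConfig(n_restarts=1, seed=5, mode="full")
        r1 = em_optimize(scrambled, "pems", coords, cfg)
        r2 = em_optimize(scrambled, "pems", coords, cfg)
        assert r1.assignments == r2.assignments
        assert r1.loss == r2.loss
        assert r1.n_sweeps == r2.n_sweeps

    def test_loss_invariant_under_global_gauge(self):
        # conjugating every geometry by one fixed signed permutation permutes
        # and sign-flips whole target columns, leaving the loss unchanged
        coords, scrambled, _ = _small_scramble_problem(2, 40)
        cfg = OptimizationConfig(n_restarts=1, seed=3, mode="full")
        res = em_optimize(scrambled, "pems", coords, cfg)
        G = SignedPermutation((2, 0, 1), (1, -1, 1))
        shifted = [s.compose(G) for s in res.assignments]
        res2 = em_optimize(scrambled, "pems", coords, cfg, initial=shifted)
        assert res2.loss == pytest.approx(res.loss, rel=1e-6)

    def test_eigenvalues_preserved_by_correction(self):
        coords, scrambled, _ = _small_scramble_problem(3, 30)
        cfg = OptimizationConfig(n_restarts=1, seed=7, mode="full")
        res = em_optimize(scrambled, "pems", coords, cfg)
        for g, s in enumerate(res.assignments):
            corrected = apply_signed_permutation(scrambled[g], s)
            assert np.allclose(
                np.linalg.eigvalsh(corrected), np.linalg.eigvalsh(scrambled[g]), atol=1e-10
            )


class TestMultistart:
    def test_single_restart_equals_em(self):
        coords, scrambled, _ = _small_scramble_problem(4, 30)
        cfg = OptimizationConfig(
            n_restarts=1, seed=9, mode="full", nested_outer_folds=3, nested_inner_folds=4
        )
        best, diag = multistart_select(scrambled, "pems", coords, cfg)
        rng = np.random.default_rng(9)
        solo = em_optimize(
            scrambled, "pems", coords,
            OptimizationConfig(n_restarts=1, seed=int(rng.integers(2**31)), mode="full"),
        )
        assert best.assignments == solo.assignments
        assert diag["n_restarts"] == 1

    def test_convex_problem_all_restarts_agree(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(25, 1))
        E = np.column_stack([0.1 * X[:, 0], 5 + 0.1 * X[:, 0]])
        cfg = OptimizationConfig(
            n_restarts=3, seed=1, repair_rounds=0, nested_outer_folds=3, nested_inner_folds=4
        )
        best, diag = multistart_select(E, "energies", X, cfg)
        assert diag["n_converged"] == 3
        assert np.allclose(diag["losses"], diag["losses"][0], atol=1e-12)

    def test_best_of_restarts_not_worse_than_median(self):
        coords, scrambled, _ = _small_scramble_problem(5, 40)
        cfg = OptimizationConfig(
            n_restarts=4, seed=2, mode="full", nested_outer_folds=3, nested_inner_folds=4
        )
        best, diag = multistart_select(scrambled, "pems", coords, cfg)
        assert diag["best_score"] <= np.median(diag["scores"])
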