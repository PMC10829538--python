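import numpy as np
import pytest

from pemlearn import synthetic
from pemlearn.overlaps import (
    CISWavefunction,
    StateDistanceMatrix,
    cis_overlap,
    determinant_overlap,
    distance_matrix_from_wavefunctions,
    silhouette_cluster,
    silhouette_mean,
    state_distance,
)


def _cofactor_det(M):
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n == 1:
        return M[0, 0]
    return sum(
        (-1) ** j * M[0, j] * _cofactor_det(np.delete(np.delete(M, 0, 0), j, 1))
        for j in range(n)
    )


class TestDeterminantOverlap:
    def test_identity_block_gives_one(self):
        assert determinant_overlap(np.eye(4)) == pytest.approx(1.0)

    def test_zero_row_gives_zero(self):
        block = np.eye(4)
        block[2] = 0.0  # an orbital orthogonal to every partner orbital
        assert determinant_overlap(block) == pytest.approx(0.0)

    def test_matches_cofactor_expansion(self, rng):
        block = rng.normal(size=(4, 4))
        assert determinant_overlap(block) == pytest.approx(_cofactor_det(block), abs=1e-12)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            determinant_overlap(np.ones((2, 3)))


def _simple_wf(coeffs, n_occ=2, n_virt=3, geometry_id=0, state_id=0, C=None):
    n_mo = n_occ + n_virt
    excitations = tuple((n_occ - 1, n_occ + v) for v in range(n_virt))
    return CISWavefunction(
        ci_coefficients=np.asarray(coeffs, dtype=float),
        excitations=excitations[: len(coeffs)],
        mo_coefficients=np.eye(n_mo) if C is None else C,
        n_occ=n_occ,
        geometry_id=geometry_id,
        state_id=state_id,
    )


class TestCISOverlap:
    def test_self_overlap_is_one(self):
        wf = _simple_wf([1.0, 0.0, 0.0])
        assert cis_overlap(wf, wf, np.eye(5)) == pytest.approx(1.0)

    def test_disjoint_excitations_orthogonal(self):
        wf1 = _simple_wf([1.0, 0.0, 0.0])
        wf2 = _simple_wf([0.0, 1.0, 0.0])
        assert cis_overlap(wf1, wf2, np.eye(5)) == pytest.approx(0.0, abs=1e-14)

    def test_rotated_ci_vectors_give_cosine(self):
        theta = 0.3
        wf1 = _simple_wf([1.0, 0.0, 0.0])
        wf2 = _simple_wf([np.cos(theta), np.sin(theta), 0.0])
        assert cis_overlap(wf1, wf2, np.eye(5)) == pytest.approx(np.cos(theta))

    def test_matches_brute_force_double_sum(self, rng):
        """Independent oracle: enumerate every spin-determinant pair explicitly
        (alpha/beta excitation combinations with 1/2 spin-adaptation weight)."""
        n_occ, n_virt = 4, 3
        n_mo = n_occ + n_virt
        # two random orthonormal MO sets in a shared AO basis + random AO metric
        A = rng.normal(size=(n_mo, n_mo))
        S_AO = A @ A.T / n_mo + np.eye(n_mo)
        L = np.linalg.cholesky(S_AO)

        def ortho_mos(seed):
            q, _ = np.linalg.qr(np.random.default_rng(seed).normal(size=(n_mo, n_mo)))
            return np.linalg.solve(L.T, q)  # C^T S_AO C = I

        C1, C2 = ortho_mos(1), ortho_mos(2)
        excitations = [(i, a) for i in range(n_occ) for a in range(n_occ, n_mo)][:5]
        c1 = rng.normal(size=5)
        c1 /= np.linalg.norm(c1)
        c2 = rng.normal(size=5)
        c2 /= np.linalg.norm(c2)
        wf1 = CISWavefunction(c1, tuple(excitations), C1, n_occ, 0, 0)
        wf2 = CISWavefunction(c2, tuple(excitations), C2, n_occ, 1, 0)

        S_MO = C1.T @ S_AO @ C2

        def det_ov(occ1, occ2):
            return np.linalg.det(S_MO[np.ix_(occ1, occ2)])

        def occ_set(exc):
            occ = list(range(n_occ))
            if exc is not None:
                occ[occ.index(exc[0])] = exc[1]
            return occ

        brute = 0.0
        for ck, ek in zip(c1, excitations):
            for cl, el in zip(c2, excitations):
                # spin-adapted singlets: (1/2) sum over alpha/beta placements
                same = det_ov(occ_set(ek), occ_set(el)) * det_ov(occ_set(None), occ_set(None))
                cross = det_ov(occ_set(ek), occ_set(None)) * det_ov(occ_set(None), occ_set(el))
                brute += ck * cl * (same + cross)
        assert cis_overlap(wf1, wf2, S_AO) == pytest.approx(brute, abs=1e-12)

    def test_complete_state_set_overlap_is_identity(self):
        wfs = [_simple_wf(np.eye(3)[i], state_id=i) for i in range(3)]
        S = np.array([[cis_overlap(a, b, np.eye(5)) for b in wfs] for a in wfs])
        assert np.allclose(S, np.eye(3), atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        wf = _simple_wf([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            cis_overlap(wf, wf, np.eye(4))


class TestStateDistance:
    @pytest.mark.parametrize("overlap,expected", [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0)])
    def test_complement_of_absolute_overlap(self, overlap, expected):
        assert state_distance(overlap) == pytest.approx(expected)

    def test_clipping_and_error(self):
        assert state_distance(1.0 + 5e-9) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            state_distance(1.1)


class TestSilhouette:
    def test_tight_separated_clusters_score_near_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.01
        d[2, 3] = d[3, 2] = 0.01
        labels = np.array([0, 0, 1, 1])
        assert silhouette_mean(d, labels) > 0.98

    def test_equidistant_point_scores_zero(self):
        d = np.array(
            [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        labels = np.array([0, 0, 1])
        # points 0,1: a = 0.5, b = 0.5 -> s = 0; singleton scores 0
        assert silhouette_mean(d, labels) == pytest.approx(0.0)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import silhouette_score

        X = rng.normal(size=(12, 2))
        d = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
        d /= d.max()
        np.fill_diagonal(d, 0.0)
        labels = rng.integers(0, 3, size=12)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, size=12)
        ours = silhouette_mean(d, labels)
        ref = silhouette_score(d, labels, metric="precomputed")
        assert ours == pytest.approx(ref, abs=1e-12)


class TestSilhouetteCluster:
    def test_recovers_toy_cis_clusters(self):
        bundle = synthetic.make_toy_cis(20, 2, seed=3)
        dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
        out = silhouette_cluster(dmat)
        agree = max(
            np.mean(out.labels == bundle.true_labels),
            np.mean(out.labels == 1 - bundle.true_labels),
        )
        assert agree == 1.0
        assert out.converged

    def test_mean_silhouette_not_decreased(self):
        bundle = synthetic.make_toy_cis(15, 2, seed=4)
        dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
        init = np.zeros(len(dmat.points), dtype=int)
        init[1::2] = 1  # energy-order style init per geometry
        out = silhouette_cluster(dmat, init_labels=init)
        assert out.mean_silhouette >= silhouette_mean(dmat.d, init) - 1e-12

    def test_optimal_clustering_is_fixed_point(self):
        bundle = synthetic.make_toy_cis(12, 2, seed=5)
        dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
        first = silhouette_cluster(dmat)
        second = silhouette_cluster(dmat, init_labels=first.labels)
        assert second.n_sweeps == 1
        assert np.array_equal(first.labels, second.labels)

    def test_two_geometries_matches_brute_force(self):
        bundle = synthetic.make_toy_cis(2, 2, seed=6)
        dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
        out = silhouette_cluster(dmat)
        # valid clusterings: geometry 1's states aligned or swapped vs geometry 0
        candidates = [np.array([0, 1, 0, 1]), np.array([0, 1, 1, 0])]
        best = max(candidates, key=lambda lab: silhouette_mean(dmat.d, lab))
        assert out.mean_silhouette == pytest.approx(silhouette_mean(dmat.d, best))

    def test_constraint_violating_init_rejected(self):
        bundle = synthetic.make_toy_cis(4, 2, seed=7)
        dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
        bad = np.zeros(len(dmat.points), dtype=int)
        with pytest.raises(ValueError):
            silhouette_cluster(dmat, init_labels=bad)

    def test_output_satisfies_exclusivity_constraint(self):
        bundle = synthetic.make_toy_cis(10, 3, seed=8)
        dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
        out = silhouette_cluster(dmat)
        for gid in dmat.geometry_ids:
            idx = dmat.indices_of_geometry(gid)
            assert len({int(out.labels[k]) for k in idx}) == len(idx)


def test_distance_matrix_is_pseudo_metric_on_fixture():
    bundle = synthetic.make_toy_cis(8, 2, seed=9)
    dmat = distance_matrix_from_wavefunctions(bundle.wavefunctions, bundle.ao_overlaps)
    d = dmat.d
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert d.min() >= 0 and d.max() <= 1 + 1e-12
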