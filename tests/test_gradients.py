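import numpy as np
import pytest
from scipy import stats

from iscn.covnet import RegionMatrix
from iscn.gradients import (
    GradientSet,
    affinity,
    diffusion_embedding,
    procrustes_align,
    variance_explained,
)


def dense_diffusion_oracle(A, alpha=0.5, n_components=3):
    """Brute-force diffusion map: explicit Markov operator, scipy.linalg.eig."""
    d = A.sum(axis=1)
    W = A / np.outer(d**alpha, d**alpha)
    P = W / W.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(evals.real)[::-1]
    evals, evecs = evals.real[order], evecs.real[:, order]
    lam = evals[1 : n_components + 1]
    vecs = evecs[:, 1 : n_components + 1]
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    return vecs * (lam / (1 - lam)), lam


def chain_affinity(n=10):
    A = np.eye(n)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 0.9
    for i in range(n - 2):
        A[i, i + 2] = A[i + 2, i] = 0.3
    return A


class TestAffinity:
    def test_identical_rows_give_one(self):
        X = np.tile(np.abs(np.random.default_rng(0).normal(0, 1, 4)), (4, 1))
        a = affinity(RegionMatrix(X, "sparsified")).values
        assert np.allclose(a, 1.0)

    def test_orthogonal_rows_give_half(self):
        X = np.eye(4)
        a = affinity(RegionMatrix(X, "sparsified")).values
        off = a[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.5)  # arccos(0)/pi = 1/2

    def test_symmetric_within_tolerance(self):
        X = np.abs(np.random.default_rng(1).normal(0, 1, (20, 20)))
        a = affinity(RegionMatrix(X, "sparsified")).values
        assert np.allclose(a, a.T, atol=1e-12)

    def test_zero_row_errors(self):
        X = np.abs(np.random.default_rng(2).normal(0, 1, (5, 5)))
        X[3] = 0.0
        with pytest.raises(ValueError, match="3"):
            affinity(RegionMatrix(X, "sparsified"))

    def test_cosine_kernel_range(self):
        X = np.abs(np.random.default_rng(3).normal(0, 1, (10, 10)))
        a = affinity(RegionMatrix(X, "sparsified"), kernel="cosine").values
        assert a.min() >= 0 and a.max() <= 1 + 1e-12


class TestDiffusionEmbedding:
    def test_chain_graph_first_gradient_monotone(self):
        gs = diffusion_embedding(RegionMatrix(chain_affinity(), "affinity"))
        rho = stats.spearmanr(gs.loadings[:, 0], np.arange(10)).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(4)
        A = np.abs(rng.normal(0, 1, (10, 10)))
        A = (A + A.T) / 2 + 2 * np.eye(10)
        gs = diffusion_embedding(RegionMatrix(A, "affinity"), n_components=3)
        oracle, lam = dense_diffusion_oracle(A, n_components=3)
        assert np.allclose(gs.eigenvalues, lam, atol=1e-8)
        for j in range(3):
            sign = np.sign(gs.loadings[:, j] @ oracle[:, j])
            assert np.allclose(gs.loadings[:, j], sign * oracle[:, j], atol=1e-8)

    def test_permutation_equivariance(self):
        A = chain_affinity()
        rng = np.random.default_rng(5)
        perm = rng.permutation(10)
        gs = diffusion_embedding(RegionMatrix(A, "affinity"), n_components=2)
        gsp = diffusion_embedding(
            RegionMatrix(A[np.ix_(perm, perm)], "affinity"), n_components=2
        )
        for j in range(2):
            sign = np.sign(gs.loadings[perm, j] @ gsp.loadings[:, j])
            assert np.allclose(gs.loadings[perm, j], sign * gsp.loadings[:, j], atol=1e-8)

    def test_two_cliques_separated_by_first_gradient(self):
        A = np.full((10, 10), 0.01)
        A[:5, :5] = 1.0
        A[5:, 5:] = 1.0
        gs = diffusion_embedding(RegionMatrix(A, "affinity"), n_components=2)
        g1 = gs.loadings[:, 0]
        assert len(np.unique(np.sign(g1[:5]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[5])

    def test_disconnected_graph_errors(self):
        A = np.eye(6)
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embedding(RegionMatrix(A, "affinity"))


class TestProcrustes:
    def _gs(self, n=20, k=4, seed=0):
        rng = np.random.default_rng(seed)
        L = rng.normal(0, 1, (n, k))
        lam = np.sort(rng.uniform(0.2, 0.9, k))[::-1]
        return GradientSet(loadings=L, eigenvalues=lam)

    def test_self_alignment_is_identity(self):
        gs = self._gs()
        aligned = procrustes_align(gs, gs, k=2)
        centered = gs.loadings[:, :2] - gs.loadings[:, :2].mean(axis=0)
        assert np.allclose(aligned.loadings, centered, atol=1e-10)
        assert aligned.aligned

    def test_recovers_known_rotation(self):
        gs = self._gs(seed=1)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        centered = gs.loadings[:, :2] - gs.loadings[:, :2].mean(axis=0)
        rotated = GradientSet(loadings=centered @ R, eigenvalues=gs.eigenvalues[:2])
        aligned = procrustes_align(rotated, gs, k=2)
        assert np.allclose(aligned.loadings, centered, atol=1e-8)

    def test_sign_flip_restored(self):
        gs = self._gs(seed=2)
        flipped = GradientSet(
            loadings=gs.loadings[:, :2] * np.array([-1.0, 1.0]),
            eigenvalues=gs.eigenvalues[:2],
        )
        aligned = procrustes_align(flipped, gs, k=2)
        centered = gs.loadings[:, :2] - gs.loadings[:, :2].mean(axis=0)
        assert np.allclose(aligned.loadings, centered, atol=1e-8)

    def test_rotation_preserves_column_norms(self):
        a, t = self._gs(seed=3), self._gs(seed=4)
        aligned = procrustes_align(a, t, k=3)
        centered = a.loadings[:, :3] - a.loadings[:, :3].mean(axis=0)
        # total centered norm is invariant under rotation
        assert np.linalg.norm(aligned.loadings) == pytest.approx(
            np.linalg.norm(centered), abs=1e-10
        )

    def test_k_too_large_errors(self):
        gs = self._gs(k=2)
        with pytest.raises(ValueError, match="exceeds"):
            procrustes_align(gs, gs, k=5)


class TestVarianceExplained:
    def test_equal_eigenvalues(self):
        gs = GradientSet(loadings=np.zeros((5, 5)), eigenvalues=np.full(5, 0.3))
        assert np.allclose(variance_explained(gs, top=5), 0.2)

    def test_three_one_split(self):
        gs = GradientSet(loadings=np.zeros((5, 2)), eigenvalues=np.array([3.0, 1.0]))
        assert np.allclose(variance_explained(gs, top=2), [0.75, 0.25])

    def test_fractions_sum_to_one(self):
        lam = np.sort(np.random.default_rng(6).uniform(0.1, 1, 7))[::-1]
        gs = GradientSet(loadings=np.zeros((9, 7)), eigenvalues=lam)
        assert variance_explained(gs, top=7).sum() == pytest.approx(1.0)
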