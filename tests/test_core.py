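import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmtsne import (
    MultiMapEmbedding,
    compute_q,
    fig_fixture_three_points,
    grad_positions,
    grad_weights,
    graph_laplacian,
    importance_weights,
    regularized_cost,
)

from conftest import random_embedding, random_joint_p


def _brute_force_q(Pi, Y):
    """Triple loop over (i, j, m): the mixture-of-Student-t similarity verbatim."""
    n, M = Pi.shape
    N = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for m in range(M):
                d = np.sum((Y[i, m] - Y[j, m]) ** 2)
                N[i, j] += Pi[i, m] * Pi[j, m] / (1.0 + d)
    Z = N.sum()
    return N / Z, Z


def _brute_force_cost(P, emb, lam):
    """Term-by-term summation of the regularized objective."""
    Q, _ = _brute_force_q(emb.pi, emb.Y)
    n = P.shape[0]
    kl = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and P[i, j] > 0:
                kl += P[i, j] * np.log(P[i, j] / Q[i, j])
    L = np.diag(P.sum(axis=1)) - P
    Pi = emb.pi
    pen = sum(float(Pi[:, m] @ L @ Pi[:, m]) for m in range(Pi.shape[1]))
    return (1 - lam) * kl + lam * pen


class TestImportanceWeights:
    def test_uniform_at_zero_omega(self):
        Pi = importance_weights(np.zeros((5, 3))).Pi
        np.testing.assert_allclose(Pi, 1 / 3, atol=1e-15)

    def test_single_map_is_one(self):
        Pi = importance_weights(np.array([[2.3], [-7.0]])).Pi
        np.testing.assert_allclose(Pi, 1.0, atol=0)

    def test_hand_evaluated_pair(self):
        # omega = (0, ln 3): exponents e^0 = 1 and e^{-ln 3} = 1/3
        Pi = importance_weights(np.array([[0.0, np.log(3.0)]])).Pi
        np.testing.assert_allclose(Pi[0], [0.75, 0.25], atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rows_are_distributions(self, seed):
        rng = np.random.default_rng(seed)
        n, M = int(rng.integers(1, 12)), int(rng.integers(1, 6))
        Omega = rng.normal(scale=10 ** rng.uniform(-2, 2), size=(n, M))
        Pi = importance_weights(Omega).Pi
        assert np.all(Pi >= 0)
        np.testing.assert_allclose(Pi.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_omega_is_stable(self):
        Pi = importance_weights(np.array([[1e4, -1e4], [-900.0, 900.0]])).Pi
        assert np.all(np.isfinite(Pi))
        np.testing.assert_allclose(Pi.sum(axis=1), 1.0, atol=1e-12)


class TestComputeQ:
    def test_disjoint_map_weights_zero_similarity(self):
        emb, expected = fig_fixture_three_points()
        q = compute_q(emb)
        assert abs(q.Q[0, 1]) < 1e-12
        assert q.Q[0, 2] > 0 and q.Q[1, 2] > 0
        assert q.Q.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(emb.pi, expected["pi"], atol=1e-15)

    def test_two_points_single_map(self):
        emb = MultiMapEmbedding(
            ids=("a", "b"), Y=np.array([[[0.0, 0.0]], [[2.0, 1.0]]]), Omega=np.zeros((2, 1))
        )
        q = compute_q(emb)
        assert q.Q[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_matches_brute_force(self, rng):
        emb = random_embedding(6, 3, rng)
        q = compute_q(emb)
        Q_ref, Z_ref = _brute_force_q(emb.pi, emb.Y)
        np.testing.assert_allclose(q.Q, Q_ref, atol=1e-12)
        assert q.Z == pytest.approx(Z_ref, rel=1e-12)

    def test_single_map_reduces_to_plain_tsne(self, rng):
        """With M=1 the weights are forced to 1 and Q is the plain Student-t Q."""
        n = 7
        emb = random_embedding(n, 1, rng)
        q = compute_q(emb)
        D = ((emb.Y[:, 0, None, :] - emb.Y[None, :, 0, :]) ** 2).sum(-1)
        K = 1.0 / (1.0 + D)
        np.fill_diagonal(K, 0.0)
        np.testing.assert_allclose(q.Q, K / K.sum(), atol=1e-12)

    def test_q_normalized_for_random_embeddings(self, rng):
        for _ in range(10):
            emb = random_embedding(
                int(rng.integers(2, 9)), int(rng.integers(1, 4)), rng
            )
            assert compute_q(emb).Q.sum() == pytest.approx(1.0, abs=1e-9)


class TestLaplacian:
    def test_two_point_hand_value(self):
        L = graph_laplacian(np.array([[0.0, 0.5], [0.5, 0.0]])).L
        np.testing.assert_allclose(L, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-15)

    def test_row_sums_zero_and_psd(self, rng):
        P = random_joint_p(9, rng)
        L = graph_laplacian(P).L
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(L, L.T, atol=1e-12)
        for _ in range(10):
            x = rng.normal(size=9)
            assert x @ L @ x >= -1e-10


class TestCost:
    def test_lambda_zero_is_pure_kl(self, rng):
        emb = random_embedding(5, 2, rng)
        c = regularized_cost(random_joint_p(5, rng), emb, lam=0.0)
        assert c.total == c.kl_term
        assert c.kl_term >= 0

    def test_kl_vanishes_when_p_equals_q(self, rng):
        emb = random_embedding(6, 2, rng)
        P = compute_q(emb).Q
        c = regularized_cost(P, emb, lam=0.0)
        assert abs(c.kl_term) < 1e-9

    def test_matches_brute_force(self, rng):
        emb = random_embedding(5, 2, rng)
        P = random_joint_p(5, rng)
        c = regularized_cost(P, emb, lam=0.1)
        assert c.total == pytest.approx(_brute_force_cost(P, emb, 0.1), rel=1e-10)
        assert c.total == pytest.approx(
            0.9 * c.kl_term + 0.1 * c.penalty_term, abs=1e-12
        )

    def test_penalty_invariant_under_map_permutation(self, rng):
        emb = random_embedding(6, 3, rng)
        P = random_joint_p(6, rng)
        perm = [2, 0, 1]
        emb_p = MultiMapEmbedding(
            ids=emb.ids, Y=emb.Y[:, perm, :], Omega=emb.Omega[:, perm]
        )
        c1 = regularized_cost(P, emb, lam=0.3)
        c2 = regularized_cost(P, emb_p, lam=0.3)
        assert c1.penalty_term == pytest.approx(c2.penalty_term, rel=1e-12)

    def test_invalid_lambda_rejected(self, rng):
        emb = random_embedding(3, 1, rng)
        with pytest.raises(ValueError):
            regularized_cost(random_joint_p(3, rng), emb, lam=1.0)


def _fd_gradients(P, emb, lam, h=1e-5):
    """Central finite differences of the total cost in every coordinate."""
    def cost(Y, Om):
        e = MultiMapEmbedding(ids=emb.ids, Y=Y, Omega=Om)
        return regularized_cost(P, e, lam).total

    gY = np.zeros_like(emb.Y)
    for idx in np.ndindex(emb.Y.shape):
        Yp, Ym = emb.Y.copy(), emb.Y.copy()
        Yp[idx] += h
        Ym[idx] -= h
        gY[idx] = (cost(Yp, emb.Omega) - cost(Ym, emb.Omega)) / (2 * h)
    gO = np.zeros_like(emb.Omega)
    for idx in np.ndindex(emb.Omega.shape):
        Op, Om_ = emb.Omega.copy(), emb.Omega.copy()
        Op[idx] += h
        Om_[idx] -= h
        gO[idx] = (cost(emb.Y, Op) - cost(emb.Y, Om_)) / (2 * h)
    return gY, gO


def _rel_err(analytic, numeric):
    scale = max(np.abs(numeric).max(), 1e-8)
    return np.abs(analytic - numeric).max() / scale


class TestGradients:
    @pytest.mark.parametrize("lam", [0.0, 0.05])
    def test_match_finite_differences(self, lam):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, M = int(rng.integers(3, 9)), int(rng.integers(1, 4))
            emb = random_embedding(n, M, rng)
            P = random_joint_p(n, rng)
            gY, gO = grad_positions(P, emb, lam), grad_weights(P, emb, lam)
            fY, fO = _fd_gradients(P, emb, lam)
            assert _rel_err(gY, fY) < 1e-4
            assert _rel_err(gO, fO) < 1e-4

    def test_zero_at_kl_minimum(self, rng):
        emb = random_embedding(2, 1, rng)
        P = compute_q(emb).Q  # Q == P: the KL is at its global minimum
        g = grad_positions(P, emb, 0.0)
        np.testing.assert_allclose(g, 0.0, atol=1e-9)

    def test_coincident_map_contributes_nothing(self, rng):
        n = 5
        Y = rng.normal(size=(n, 2, 2))
        Y[:, 0, :] = 1.3  # all points coincide in map 0
        emb = MultiMapEmbedding(
            ids=tuple(map(str, range(n))), Y=Y, Omega=rng.normal(size=(n, 2))
        )
        g = grad_positions(random_joint_p(n, rng), emb, 0.0)
        np.testing.assert_allclose(g[:, 0, :], 0.0, atol=1e-15)

    def test_single_map_weight_gradient_vanishes(self, rng):
        emb = random_embedding(6, 1, rng)
        g = grad_weights(random_joint_p(6, rng), emb, 0.05)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_map_swap_symmetry(self, rng):
        """Identical positions in both maps: swapping omega columns swaps the
        gradient columns (the objective is symmetric in the two maps)."""
        n = 5
        Y1 = rng.normal(size=(n, 1, 2))
        Y = np.concatenate([Y1, Y1], axis=1)
        Om = rng.normal(size=(n, 2))
        P = random_joint_p(n, rng)
        ids = tuple(map(str, range(n)))
        g = grad_weights(P, MultiMapEmbedding(ids=ids, Y=Y, Omega=Om), 0.1)
        g_sw = grad_weights(
            P, MultiMapEmbedding(ids=ids, Y=Y, Omega=Om[:, ::-1]), 0.1
        )
        np.testing.assert_allclose(g_sw, g[:, ::-1], atol=1e-10)
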