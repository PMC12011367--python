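import numpy as np
import pytest

from netcoreg.embedding import (
    build_A,
    build_E,
    standardize,
    svd_embed,
)
from netcoreg.ppin import CandidateSet, PPINetwork, subset_and_complete

from conftest import random_complete_ppin


def network_penalty_brute(W, d, c):
    """Independent double-loop evaluation of sum_{i<j} w_ij (c_i/sqrt(d_i)-c_j/sqrt(d_j))^2."""
    n = len(c)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += W[i, j] * (c[i] / np.sqrt(d[i]) - c[j] / np.sqrt(d[j])) ** 2
    return total


def make_problem(seed=0, m=120, n=6):
    rng = np.random.default_rng(seed)
    X_raw = rng.standard_normal((m, n)) @ rng.standard_normal((n, n))
    y_raw = rng.standard_normal(m)
    X, y = standardize(X_raw, y_raw)
    ppin = random_complete_ppin(rng, n)
    return X, y, ppin


class TestStandardize:
    def test_hand_computed_column(self):
        X, y = standardize(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 9.0]))
        assert X.X[:, 0] == pytest.approx([-1.224744871, 0.0, 1.224744871], abs=1e-9)

    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(3)
        X, y = standardize(rng.standard_normal((50, 4)) * 7 + 2, rng.standard_normal(50))
        assert np.allclose(X.X.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(X.X.std(axis=0), 1, atol=1e-8)
        X2, _ = standardize(X.X, y.y)
        assert np.allclose(X2.X, X.X, atol=1e-12)

    def test_pearson_correlations_preserved(self):
        rng = np.random.default_rng(4)
        raw = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 3)) + 5
        X, _ = standardize(raw, rng.standard_normal(200))
        assert np.allclose(np.corrcoef(raw.T), np.corrcoef(X.X.T), atol=1e-10)

    def test_zero_variance_column_names_tf(self):
        bad = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="TF1"):
            standardize(bad, np.arange(10.0), tf_order=("TF1", "TF2"))
        with pytest.raises(ValueError, match="constant"):
            standardize(np.arange(10.0)[:, None], np.ones(10))

    def test_training_transform_applies_to_heldout(self):
        rng = np.random.default_rng(5)
        train, test = rng.standard_normal((30, 2)) * 3 + 1, rng.standard_normal((10, 2))
        X, _ = standardize(train, rng.standard_normal(30))
        assert np.allclose(X.transform(test), (test - X.col_means) / X.col_sds)


class TestPenaltyMatrix:
    def test_two_node_network(self):
        net = PPINetwork({frozenset(("A", "B")): 0.5})
        ppin = subset_and_complete(net, CandidateSet(tg="TG", tfs=("A", "B")))
        assert np.allclose(build_A(ppin).A, [[1, -1], [-1, 1]])

    def test_five_tf_entry(self, five_tf_ppin):
        A = build_A(five_tf_ppin).A
        assert A[0, 1] == pytest.approx(-0.8 / 0.83)

    def test_unit_diagonal_and_negative_offdiag(self):
        rng = np.random.default_rng(11)
        for n in (3, 7, 15):
            A = build_A(random_complete_ppin(rng, n)).A
            assert np.allclose(np.diag(A), 1.0)
            off = A[~np.eye(n, dtype=bool)]
            assert np.all(off < 0) and np.all(off >= -1)

    def test_sqrt_degree_null_vector(self, five_tf_ppin):
        pm = build_A(five_tf_ppin)
        assert np.allclose(pm.A @ np.sqrt(pm.d), 0, atol=1e-10)

    def test_quadratic_form_matches_brute_force(self, five_tf_ppin):
        pm = build_A(five_tf_ppin)
        rng = np.random.default_rng(12)
        for _ in range(10):
            c = rng.standard_normal(5) * 3
            brute = network_penalty_brute(five_tf_ppin.W, pm.d, c)
            assert abs(brute - c @ pm.A @ c) < 1e-10

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(13)
        A = build_A(random_complete_ppin(rng, 10)).A
        assert np.linalg.eigvalsh(A).min() >= -1e-10


class TestCombinedMatrix:
    def test_diagonal_is_one_plus_beta(self):
        X, y, ppin = make_problem()
        E = build_E(X, build_A(ppin), beta=2.5)
        assert np.allclose(np.diag(E), 3.5, atol=1e-10)

    def test_beta_floor_recovers_correlation_matrix(self):
        X, y, ppin = make_problem(seed=1)
        E = build_E(X, build_A(ppin), beta=0.0)  # replaced by the floor
        assert np.allclose(E, np.corrcoef(X.X.T), atol=1e-5)

    def test_positive_semidefinite(self):
        X, y, ppin = make_problem(seed=2)
        E = build_E(X, build_A(ppin), beta=1.0)
        assert np.linalg.eigvalsh(E).min() >= -1e-8

    def test_dimension_mismatch(self, five_tf_ppin):
        X, y, _ = make_problem(n=4)
        with pytest.raises(ValueError, match="mismatch"):
            build_E(X, build_A(five_tf_ppin), beta=1.0)


class TestEmbedding:
    def test_reconstruction_identities(self):
        """1/N X~'X~ = E and 1/N y~'X~ = 1/M y'X without truncation."""
        X, y, ppin = make_problem(seed=6)
        E = build_E(X, build_A(ppin), beta=1.0)
        emb = svd_embed(E, X, y, beta=1.0)
        n = emb.n
        assert np.allclose(emb.X_tilde.T @ emb.X_tilde / n, E, atol=1e-8)
        assert np.allclose(emb.y_tilde @ emb.X_tilde / n, y.y @ X.X / X.m, atol=1e-8)

    def test_embedded_objective_equals_original(self):
        """The transformed Lasso objective equals the network-regularized one
        plus the fixed constant, on random coefficient vectors."""
        X, y, ppin = make_problem(seed=7, m=200, n=8)
        beta = 0.7
        pm = build_A(ppin)
        E = build_E(X, pm, beta)
        emb = svd_embed(E, X, y, beta=beta)
        assert emb.rank_retained == emb.n
        m, n = X.m, emb.n
        const = (y.y @ y.y) / (2 * m) - (emb.y_tilde @ emb.y_tilde) / (2 * n)
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = rng.standard_normal(n)
            orig = (np.sum((y.y - X.X @ c) ** 2) / (2 * m)
                    + beta / 2 * c @ pm.A @ c)
            trans = np.sum((emb.y_tilde - emb.X_tilde @ c) ** 2) / (2 * n) + const
            assert abs(orig - trans) < 1e-6

    def test_beta_floor_aligns_with_principal_components(self):
        X, y, ppin = make_problem(seed=9, m=300, n=5)
        E = build_E(X, build_A(ppin), beta=0.0)
        emb = svd_embed(E, X, y, beta=1e-6)
        _, _, Vt = np.linalg.svd(X.X, full_matrices=False)
        for k in range(emb.rank_retained):
            row = emb.X_tilde[k]
            cos = abs(row @ Vt[k]) / np.linalg.norm(row)
            assert cos >= 0.999

    def test_identity_E(self):
        X, y, _ = make_problem(seed=10, n=4)
        emb = svd_embed(np.eye(4), X, y, beta=1.0)
        assert np.allclose(emb.S, 1.0)
        assert np.allclose(emb.X_tilde.T @ emb.X_tilde, 4 * np.eye(4), atol=1e-10)

    def test_cosine_closed_form(self):
        """cos(X~_i, X~_j) = E_ij / sqrt(E_ii E_jj) without truncation."""
        X, y, ppin = make_problem(seed=14, n=6)
        E = build_E(X, build_A(ppin), beta=1.0)
        emb = svd_embed(E, X, y, beta=1.0)
        G = emb.X_tilde.T @ emb.X_tilde
        norms = np.sqrt(np.diag(G))
        cos = G / np.outer(norms, norms)
        expected = E / np.sqrt(np.outer(np.diag(E), np.diag(E)))
        assert np.allclose(cos, expected, atol=1e-8)

    def test_truncation_zeroes_small_directions(self):
        X, y, _ = make_problem(seed=15, n=4)
        base = np.diag([4.0, 2.0, 1.0, 1e-9])
        emb = svd_embed(base, X, y, beta=1.0, tol=1e-6)
        assert emb.rank_retained == 3
        assert emb.S_trunc[3] == 0.0 and emb.y_tilde[3] == 0.0

    def test_degenerate_E_rejected(self):
        X, y, _ = make_problem(seed=16, n=3)
        with pytest.raises(ValueError, match="degenerate"):
            svd_embed(np.zeros((3, 3)), X, y, beta=1.0)

    def test_bad_tol_rejected(self):
        X, y, ppin = make_problem(seed=17)
        E = build_E(X, build_A(ppin), beta=1.0)
        with pytest.raises(ValueError, match="tol"):
            svd_embed(E, X, y, beta=1.0, tol=2.0)
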