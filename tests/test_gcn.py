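import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from nichetraj import RunConfig
from nichetraj.gcn import (
    GraphData,
    cluster_assignment,
    gcn_forward,
    init_params,
    modularity_loss,
    normalize_adjacency,
    purity_loss,
    regularization_loss,
    selu,
    total_loss_and_grads,
    train,
)


def random_row_stochastic(rng, n, k):
    C = rng.uniform(0.01, 1, size=(n, k))
    return C / C.sum(axis=1, keepdims=True)


class TestNormalizeAdjacency:
    def test_single_edge_is_unchanged(self):
        A = np.array([[0, 1], [1, 0]], dtype=float)
        np.testing.assert_allclose(normalize_adjacency(A).toarray(), A)

    def test_star_graph_closed_form(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1
        An = normalize_adjacency(A).toarray()
        np.testing.assert_allclose(An[0, 1:], 1 / np.sqrt(3))
        assert (An[1:, 1:] == 0).all()

    def test_spectrum_in_unit_interval(self, rng):
        A = (rng.uniform(size=(50, 50)) < 0.1).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        eig = np.linalg.eigvalsh(normalize_adjacency(A).toarray())
        assert eig.min() >= -1 - 1e-10 and eig.max() <= 1 + 1e-10

    def test_isolated_node_row_is_zero(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1
        An = normalize_adjacency(A).toarray()
        assert (An[2] == 0).all() and (An[:, 2] == 0).all()


class TestForward:
    def test_zero_weights_give_zero_embedding_uniform_assignment(self, rng):
        V = random_row_stochastic(rng, 6, 3)
        P = sparse.identity(6, format="csr")
        params = {"W1": np.zeros((3, 4)), "W2": np.zeros((4, 4)), "Wc": np.zeros((4, 5))}
        X2, C = gcn_forward(V, P, params, beta=0.03)
        assert (X2 == 0).all()
        np.testing.assert_allclose(C, 1 / 5)

    def test_single_isolated_node_identity_weights(self):
        v = np.array([[0.2, 0.5, 0.3]])
        P = sparse.identity(1, format="csr")
        params = {"W1": np.eye(3), "W2": np.eye(3), "Wc": np.zeros((3, 2))}
        X2, _ = gcn_forward(v, P, params, beta=1.0)
        np.testing.assert_allclose(X2, selu(selu(v)))

    def test_matches_scalar_loop_oracle_on_path_graph(self, rng):
        n, m, h = 5, 3, 4
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1
        P = (normalize_adjacency(A) + sparse.identity(n)).toarray()
        V = random_row_stochastic(rng, n, m)
        params = init_params(m, h, 2, rng)
        X2, _ = gcn_forward(V, sparse.csr_matrix(P), params, beta=0.03)
        # scalar re-evaluation of SeLU((A~+I) SeLU((A~+I) V W1) W2)
        Z1 = np.zeros((n, h))
        for i in range(n):
            for j in range(h):
                Z1[i, j] = sum(
                    P[i, a] * V[a, b] * params["W1"][b, j]
                    for a in range(n) for b in range(m)
                )
        X1 = selu(Z1)
        Z2 = np.zeros((n, h))
        for i in range(n):
            for j in range(h):
                Z2[i, j] = sum(
                    P[i, a] * X1[a, b] * params["W2"][b, j]
                    for a in range(n) for b in range(h)
                )
        np.testing.assert_allclose(X2, selu(Z2), atol=1e-12)


class TestClusterAssignment:
    def test_zero_head_gives_uniform(self, rng):
        X2 = rng.normal(size=(7, 4))
        np.testing.assert_allclose(cluster_assignment(X2, np.zeros((4, 3)), 0.03), 1 / 3)

    def test_large_beta_approaches_one_hot(self):
        X2 = np.array([[1.0, 0.0]])
        Wc = np.eye(2)
        C = cluster_assignment(X2, Wc, beta=1e4)
        np.testing.assert_allclose(C, [[1.0, 0.0]], atol=1e-10)

    def test_known_softmax_values(self):
        X2 = np.array([[1.0, 2.0, 3.0]])
        C = cluster_assignment(X2, np.eye(3), beta=1.0)
        np.testing.assert_allclose(C[0], [0.09003057, 0.24472847, 0.66524096], atol=1e-7)

    def test_rows_sum_to_one_and_positive(self, rng):
        C = cluster_assignment(rng.normal(size=(20, 4)), rng.normal(size=(4, 6)), 0.03)
        np.testing.assert_allclose(C.sum(axis=1), 1.0)
        assert (C > 0).all()


def scalar_modularity(C, A):
    """Direct evaluation of -Tr(C^T B C)/(2N), B = A - d d^T/(2N)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    d = A.sum(axis=1)
    B = A - np.outer(d, d) / (2 * n)
    return -np.trace(C.T @ B @ C) / (2 * n)


class TestModularityLoss:
    def test_edgeless_graph_is_zero(self, rng):
        C = random_row_stochastic(rng, 6, 3)
        assert modularity_loss(C, np.zeros((6, 6))) == 0.0

    def test_triangle_single_cluster_is_zero(self):
        A = np.ones((3, 3)) - np.eye(3)
        C = np.ones((3, 1))
        # with the 2N convention, 2m = 2N when m = N = 3: loss vanishes
        assert modularity_loss(C, A) == pytest.approx(0.0, abs=1e-12)
        assert scalar_modularity(C, A) == pytest.approx(0.0, abs=1e-12)

    def test_component_alignment_beats_mixing(self):
        # two disjoint triangles; hard component-matching C vs a mixed C
        A = np.zeros((6, 6))
        for off in (0, 3):
            for i in range(3):
                for j in range(3):
                    if i != j:
                        A[off + i, off + j] = 1
        aligned = np.zeros((6, 2))
        aligned[:3, 0] = aligned[3:, 1] = 1
        mixed = np.zeros((6, 2))
        mixed[::2, 0] = mixed[1::2, 1] = 1
        assert modularity_loss(aligned, A) < modularity_loss(mixed, A)
        assert modularity_loss(aligned, A) == pytest.approx(scalar_modularity(aligned, A))

    def test_matches_scalar_oracle_random(self, rng):
        A = (rng.uniform(size=(15, 15)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        C = random_row_stochastic(rng, 15, 4)
        assert modularity_loss(C, A) == pytest.approx(scalar_modularity(C, A))


class TestPurityLoss:
    def test_homogeneous_compositions_give_zero(self, rng):
        V = np.tile([0.3, 0.7], (8, 1))
        C = random_row_stochastic(rng, 8, 3)
        assert purity_loss(C, V) == pytest.approx(0.0, abs=1e-12)

    def test_separated_hard_clusters_give_zero(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        C = np.eye(2)
        assert purity_loss(C, V) == pytest.approx(0.0, abs=1e-12)

    def test_forced_merge_hand_value(self):
        # both niches in one cluster: centroid (0.5, 0.5), MSE = 0.25
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        C = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert purity_loss(C, V) == pytest.approx(0.25)

    def test_invariant_to_cluster_permutation(self, rng):
        V = random_row_stochastic(rng, 10, 3)
        C = random_row_stochastic(rng, 10, 4)
        perm = rng.permutation(4)
        assert purity_loss(C, V) == pytest.approx(purity_loss(C[:, perm], V))


class TestRegularizationLoss:
    def test_uniform_assignment_lower_bound(self):
        C = np.full((7, 4), 0.25)
        assert regularization_loss(C) == pytest.approx(1 / 3)

    def test_one_hot_upper_bound(self, rng):
        C = np.eye(5)[rng.integers(0, 5, size=12)]
        assert regularization_loss(C) == pytest.approx(5 / 4)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 8), st.integers(1, 30))
    def test_bounds_for_any_row_stochastic_c(self, seed, k, n):
        rng = np.random.default_rng(seed)
        C = random_row_stochastic(rng, n, k)
        val = regularization_loss(C)
        assert 1 / (k - 1) - 1e-12 <= val <= k / (k - 1) + 1e-12


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        """Central finite differences on all parameters, 10-niche instance."""
        n, m = 10, 3
        A = (rng.uniform(size=(n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        V = random_row_stochastic(rng, n, m)
        config = RunConfig(k_neighbors=5, sigma_index=3, n_clusters=4, seed=0)

        class FakeNW:
            adjacency = sparse.csr_matrix(A)
            composition = V

        graph = GraphData.from_network(FakeNW)
        params = init_params(m, config.hidden_dim, config.n_clusters, rng)
        _, grads = total_loss_and_grads(graph, params, config)

        def loss_at(p):
            rep, _ = total_loss_and_grads(graph, p, config)
            return rep.L_total

        eps = 1e-6
        for name in params:
            num = np.zeros_like(params[name])
            for idx in np.ndindex(params[name].shape):
                p_hi = {k: v.copy() for k, v in params.items()}
                p_lo = {k: v.copy() for k, v in params.items()}
                p_hi[name][idx] += eps
                p_lo[name][idx] -= eps
                num[idx] = (loss_at(p_hi) - loss_at(p_lo)) / (2 * eps)
            denom = max(np.abs(num).max(), np.abs(grads[name]).max(), 1e-8)
            rel = np.abs(num - grads[name]).max() / denom
            assert rel < 1e-4, f"{name}: relative gradient error {rel}"


class TestTraining:
    def test_loss_trace_finite_and_improving(self, small_results):
        loss = small_results.loss_frame()
        assert np.isfinite(loss[["L_m", "L_p", "L_r", "L_total"]].to_numpy()).all()
        assert loss["L_total"].iloc[-1] <= loss["L_total"].iloc[0]
        # L_r stays inside its closed-form bounds
        k = small_results.config.n_clusters
        assert loss["L_r"].between(1 / (k - 1) - 1e-9, k / (k - 1) + 1e-9).all()

    def test_two_pure_blobs_separate_with_k2(self):
        """Two distant pure-type blobs must land in different clusters."""
        import pandas as pd
        from nichetraj import NicheTrajectory

        rng = np.random.default_rng(3)
        n_half = 60
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(2 * n_half)],
                "sample": "s",
                "x": np.r_[rng.normal(0, 1, n_half), rng.normal(60, 1, n_half)],
                "y": rng.normal(0, 1, 2 * n_half),
                "cell_type": ["A"] * n_half + ["B"] * n_half,
            }
        )
        cfg = RunConfig(k_neighbors=10, sigma_index=5, n_clusters=2,
                        max_epochs=300, seed=3)
        res = NicheTrajectory.from_dataframe(cells, cfg).fit()
        labels = res.assignments.argmax(axis=1)
        assert len(set(labels[:n_half])) == 1
        assert len(set(labels[n_half:])) == 1
        assert labels[0] != labels[-1]

    def test_same_seed_reproduces_parameters(self, small_dataset):
        from nichetraj import NicheTrajectory

        cfg = RunConfig(k_neighbors=20, sigma_index=10, max_epochs=40, seed=11)
        r1 = NicheTrajectory.from_dataframe(small_dataset.cells, cfg).fit()
        r2 = NicheTrajectory.from_dataframe(small_dataset.cells, cfg).fit()
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])
        np.testing.assert_array_equal(r1.cell_scores, r2.cell_scores)
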