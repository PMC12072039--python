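"""The PPI branch: node embedding, linear attention, residual GCN.

Every matrix-form stage is checked against a brute-force twin: a dense
oracle for the linear attention and an explicit per-node loop for the
GCN layer; permutation equivariance ties the whole branch together.
"""

import numpy as np
import pytest
from scipy import sparse as sp

from gtgo.core_data import ValidationError
from gtgo.graph_transformer import (
    GraphBranchParameters,
    embed_nodes,
    frobenius_normalize,
    gcn_forward,
    gcn_layer,
    gcn_nodewise_oracle,
    init_graph_branch_params,
    normalize_adjacency,
    ppi_embedding,
    sga_dense_oracle,
    sga_linear,
    transformer_encoder,
)

from conftest import make_network, random_network


def params_for(m, d, rng, **kw):
    return init_graph_branch_params(m, d, rng, **kw)


class TestEmbedNodes:
    def test_zero_input_broadcasts_bias(self, rng):
        p = params_for(3, 4, rng)
        p.b0 = rng.standard_normal(4)
        H = embed_nodes(np.zeros((5, 3)), p).values
        expect = np.maximum(p.b0, 0)
        assert np.allclose(H, np.tile(expect, (5, 1)))

    def test_identity_case_with_hook(self, rng):
        p = params_for(3, 3, rng, activation="identity")
        p.W0 = np.eye(3)
        p.b0 = np.zeros(3)
        assert np.allclose(embed_nodes(np.eye(3), p).values, np.eye(3))

    def test_matches_triple_loop_oracle(self, rng):
        X = rng.standard_normal((4, 3))
        p = params_for(3, 5, rng)
        H = embed_nodes(X, p).values
        expect = np.empty((4, 5))
        for i in range(4):
            for j in range(5):
                acc = p.b0[j]
                for k in range(3):
                    acc += X[i, k] * p.W0[k, j]
                expect[i, j] = max(acc, 0.0)
        assert np.abs(H - expect).max() < 1e-12

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            embed_nodes(np.zeros((2, 4)), params_for(3, 5, rng))


class TestFrobeniusNormalize:
    def test_unit_norm_output(self, rng):
        M = rng.standard_normal((5, 4))
        assert abs(np.linalg.norm(frobenius_normalize(M)) - 1) < 1e-12

    def test_scaled_identity_closed_form(self):
        assert np.allclose(frobenius_normalize(2 * np.eye(2)), np.eye(2) / np.sqrt(2))

    def test_matches_loop_oracle(self, rng):
        M = rng.standard_normal((5, 4))
        ss = 0.0
        for row in M:
            for v in row:
                ss += v * v
        assert np.allclose(frobenius_normalize(M), M / np.sqrt(ss))

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            frobenius_normalize(np.zeros((2, 2)))


class TestSGA:
    def test_single_node_closed_form(self, rng):
        # N=1: numerator v*(1+q.k) and D=1+q.k cancel, leaving V + H0
        p = params_for(3, 3, rng)
        H = rng.standard_normal((1, 3))
        V = H @ p.Wv + p.bv
        assert np.abs(sga_linear(H, p).values - (V + H)).max() < 1e-12

    def test_antisymmetric_keys_zero_column_sum(self, rng):
        # rows of K sum to zero => K~^T 1_N = 0 => D = I
        d = 4
        p = params_for(d, d, rng, activation="identity")
        p.Wk = np.eye(d)
        p.bk = np.zeros(d)
        row = rng.standard_normal(d) + 1.0
        H = np.vstack([row, -row])  # K = H is antisymmetric across nodes
        Q = H @ p.Wq + p.bq
        V = H @ p.Wv + p.bv
        Qn = frobenius_normalize(Q)
        Kn = frobenius_normalize(H)
        expect = V + 0.5 * (Qn @ (Kn.T @ V)) + H
        assert np.abs(sga_linear(H, p).values - expect).max() < 1e-10

    def test_matches_dense_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(3, 65))
            d = int(rng.integers(2, 17))
            p = params_for(d, d, rng)
            H = rng.standard_normal((n, d))
            dev = np.abs(sga_linear(H, p).values - sga_dense_oracle(H, p).values).max()
            worst = max(worst, dev)
        assert worst <= 1e-5

    def test_dense_oracle_row_normalizer_is_its_diagonal(self, rng):
        # D_ii = 1 + (1/N) sum_j q~_i . k~_j, straight from the dense scores
        d, n = 5, 7
        p = params_for(d, d, rng)
        H = rng.standard_normal((n, d))
        Q = frobenius_normalize(H @ p.Wq + p.bq)
        K = frobenius_normalize(H @ p.Wk + p.bk)
        P = (Q @ K.T) / n
        dvec = 1 + P.sum(axis=1)
        for i in range(n):
            assert dvec[i] == pytest.approx(1 + sum(Q[i] @ K[j] for j in range(n)) / n)

    def test_permutation_equivariance(self, rng):
        d, n = 4, 9
        p = params_for(d, d, rng)
        H = rng.standard_normal((n, d))
        perm = rng.permutation(n)
        out = sga_linear(H, p).values
        out_p = sga_linear(H[perm], p).values
        assert np.abs(out_p - out[perm]).max() < 1e-10

    def test_oracle_guard(self, rng):
        p = params_for(2, 2, rng)
        with pytest.raises(ValidationError):
            sga_dense_oracle(np.ones((2049, 2)), p)


class TestTransformerEncoder:
    def test_constant_row_layernorm_gives_shift(self, rng):
        d = 4
        p = params_for(d, d, rng, activation="identity")
        # identity MLP hook: out = LN(SGA(H0))
        p.mlp_W1 = np.eye(d)
        p.mlp_b1 = np.zeros(d)
        p.mlp_W2 = np.eye(d)
        p.mlp_b2 = np.zeros(d)
        # rig SGA to produce a constant row: N=1 => SGA = V + H0
        p.Wv = np.zeros((d, d))
        p.bv = np.zeros(d) + 1e-9  # avoid zero-matrix normalization error? V not normalized
        H = np.full((1, d), 3.0)
        out = transformer_encoder(H, p).values
        assert np.abs(out).max() < 1e-6  # scale 1, shift 0 -> zero row

    def test_equals_stage_composition(self, rng):
        d, n = 5, 8
        p = params_for(d, d, rng)
        H = rng.standard_normal((n, d))
        sga = sga_linear(H, p).values
        mu = sga.mean(axis=1, keepdims=True)
        var = ((sga - mu) ** 2).mean(axis=1, keepdims=True)
        ln = (sga - mu) / np.sqrt(var + 1e-5) * p.ln_scale + p.ln_shift
        mlp = np.maximum(ln @ p.mlp_W1 + p.mlp_b1, 0) @ p.mlp_W2 + p.mlp_b2
        assert np.abs(transformer_encoder(H, p).values - mlp).max() < 1e-10

    def test_outer_residual_flag_changes_input_to_ln(self, rng):
        d = 3
        p = params_for(d, d, rng)
        H = np.abs(np.random.default_rng(0).standard_normal((4, d)))
        base = transformer_encoder(H, p).values
        p.encoder_outer_residual = True
        alt = transformer_encoder(H, p).values
        assert np.abs(base - alt).max() > 1e-8


class TestNormalizeAdjacency:
    def test_edgeless_network_gives_identity(self):
        net = make_network(np.zeros((4, 4)))
        assert np.allclose(normalize_adjacency(net).values.toarray(), np.eye(4))

    def test_two_node_unit_weight_closed_form(self):
        net = make_network([[0, 1], [1, 0]])
        assert np.allclose(normalize_adjacency(net).values.toarray(), np.full((2, 2), 0.5))

    def test_path_matches_loop_oracle(self):
        net = make_network([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
        A_t = net.adjacency.toarray() + np.eye(3)
        deg = A_t.sum(axis=1)
        expect = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                expect[i, j] = A_t[i, j] / np.sqrt(deg[i] * deg[j])
        assert np.abs(normalize_adjacency(net).values.toarray() - expect).max() < 1e-12

    def test_symmetric_and_positive_diagonal(self, rng):
        net = random_network(rng, 12)
        A_hat = normalize_adjacency(net).values
        assert abs(A_hat - A_hat.T).max() < 1e-12
        assert (A_hat.diagonal() > 0).all()


class TestGCN:
    def test_edgeless_doubling(self, rng):
        net = make_network(np.zeros((3, 3)))
        H = np.abs(rng.standard_normal((3, 4)))
        out = gcn_layer(H, normalize_adjacency(net), np.eye(4))
        assert np.allclose(out, 2 * H)

    def test_zero_weights_residual_only(self, rng):
        net = random_network(rng, 5)
        H = rng.standard_normal((5, 3))
        assert np.allclose(gcn_layer(H, normalize_adjacency(net), np.zeros((3, 3))), H)

    def test_matches_nodewise_oracle_on_100_random_graphs(self):
        rng = np.random.default_rng(77)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(2, 65))
            d = int(rng.integers(2, 9))
            net = random_network(rng, n)
            H = rng.standard_normal((n, d))
            W = rng.standard_normal((d, d))
            a = gcn_layer(H, normalize_adjacency(net), W)
            b = gcn_nodewise_oracle(H, net, W)
            worst = max(worst, np.abs(a - b).max())
        assert worst <= 1e-6

    def test_single_isolated_node(self, rng):
        net = make_network(np.zeros((1, 1)))
        H = rng.standard_normal((1, 3))
        W = rng.standard_normal((3, 3))
        out = gcn_nodewise_oracle(H, net, W)
        assert np.allclose(out, H + np.maximum(H @ W, 0))

    def test_permutation_equivariance(self, rng):
        n, d = 8, 3
        net = random_network(rng, n)
        H = rng.standard_normal((n, d))
        W = rng.standard_normal((d, d))
        perm = rng.permutation(n)
        permuted = make_network(net.adjacency.toarray()[np.ix_(perm, perm)])
        out = gcn_layer(H, normalize_adjacency(net), W)
        out_p = gcn_layer(H[perm], normalize_adjacency(permuted), W)
        assert np.abs(out_p - out[perm]).max() < 1e-10

    def test_forward_is_layer_composition(self, rng):
        net = random_network(rng, 6)
        p = params_for(4, 4, rng)
        H = rng.standard_normal((6, 4))
        A_hat = normalize_adjacency(net)
        manual = gcn_layer(gcn_layer(H, A_hat, p.gcn_weights[0]), A_hat, p.gcn_weights[1])
        assert np.allclose(gcn_forward(H, A_hat, p).values, manual)

    def test_forward_zero_weights_is_identity_on_h0(self, rng):
        net = random_network(rng, 5)
        p = params_for(4, 4, rng)
        p.gcn_weights = [np.zeros((4, 4)), np.zeros((4, 4))]
        H = rng.standard_normal((5, 4))
        assert np.allclose(gcn_forward(H, normalize_adjacency(net), p).values, H)


class TestPPIEmbedding:
    def test_blocks_recoverable_by_slicing(self, rng):
        from gtgo.graph_transformer import EmbeddingMatrix

        a = EmbeddingMatrix(rng.standard_normal((4, 2)), role="H_GCN_2")
        b = EmbeddingMatrix(rng.standard_normal((4, 2)), role="H_Trans")
        out = ppi_embedding(a, b)
        assert out.values.shape == (4, 4)
        assert np.array_equal(out.values[:, :2], a.values)
        assert np.array_equal(out.values[:, 2:], b.values)

    def test_row_mismatch_rejected(self, rng):
        from gtgo.graph_transformer import EmbeddingMatrix

        with pytest.raises(ValidationError):
            ppi_embedding(
                EmbeddingMatrix(np.zeros((3, 2)), role="H_GCN_2"),
                EmbeddingMatrix(np.zeros((4, 2)), role="H_Trans"),
            )


def test_full_branch_permutation_equivariance(rng):
    """Relabeling proteins permutes the rows of H_PPI."""
    n, m, d = 10, 6, 4
    net = random_network(rng, n)
    X = (rng.random((n, m)) < 0.4).astype(float)
    p = params_for(m, d, rng)
    perm = rng.permutation(n)

    def branch(net_, X_):
        H0 = embed_nodes(X_, p)
        A_hat = normalize_adjacency(net_)
        return ppi_embedding(gcn_forward(H0, A_hat, p), transformer_encoder(H0, p)).values

    out = branch(net, X)
    net_p = make_network(net.adjacency.toarray()[np.ix_(perm, perm)])
    out_p = branch(net_p, X[perm])
    assert np.abs(out_p - out[perm]).max() < 1e-8
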